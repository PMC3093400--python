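# Methods

`ifacesim` measures, learns, classifies and retrieves structural
similarity between protein–protein interaction interfaces. This note
records the models implemented, the parameters that matter, and the
design decisions taken where the published procedures leave latitude.

## Interfaces

An interaction is a pair of subunits (chains, or `chain:start-end`
residue ranges for intra-chain domain–domain contacts) in one
coordinate frame. Residues are in contact when any two of their atoms
lie within the contact cutoff, **6 Å inclusive** (the common
convention; all atoms present in the file are used, hydrogens
included when present). The binding sites are the contact-residue
projections, and the interface is the triple (site A, site B, contact
pairs). Waters and ligands never mediate contacts; modified residues
are mapped to their parent amino acid when the chemical-component
tables declare one, otherwise skipped and logged. Alternate locations
resolve to the highest-occupancy conformer.

## Structure-based measures

**iiRMSD** compares binding modes through whole-subunit superposition.
For each of the four subunit pairings, the paired subunits are
structurally aligned, the Cα RMSD over corresponded binding-site
residues is computed, the same transform is applied to the remaining
two subunits, their binding-site Cα RMSD is added, and the two values
are averaged (unweighted mean); the minimum over the four scenarios is
reported, ties broken in scenario order A1–B1, A1–B2, A2–B1, A2–B2. A
correspondence pair enters a site RMSD when **either** of its residues
is a site residue — this is essential for native–decoy comparisons,
where the decoy's binding site involves different residues and an
overlap-only comparison would shrink to nothing. When the remaining
subunits cannot be structurally aligned (common-partner analogous
pairs), their correspondence is the minimum-cost one-to-one pairing of
binding-site Cα atoms under the scenario transform (Hungarian
assignment); this keeps the measure defined exactly where the
original protocol needs it to be.

**siRMSD** aligns only the pooled interface residues (site identity
preserved; both site-to-site orientations tried, best kept) and
reports the Cα RMSD over the correspondence.

Both measures snap values below 1 nÅ to exactly 0, so self-comparisons
return 0 rather than floating-point dust.

### Alignment provider

The reference implementation used a closed-source sequence-order-
independent aligner. The built-in provider is: global identity-scored
sequence alignment (match 1, mismatch 0, gap −0.5) as a seed, then
iterative Kabsch refinement re-pairing mutual-nearest Cα atoms within
5 Å, to convergence or 20 rounds. When the refined correspondence
covers less than the required fraction of the shorter subunit, the
provider falls back to seeding from 12-residue fragment pairs (stride
3), pre-screened by fragment RMSD with the best 12 seeds refined.
Success requires **60 %** coverage by default. Corpus-scale pipelines
use **40 %**: the fragment provider is stricter than the reference
sequence-order-independent aligners, which routinely return partial
alignments of structurally unrelated proteins — without the lower
threshold, native–native dissimilar pairs would have no defined iiRMSD
at all. Any aligner returning a correspondence plus a rigid transform
can be plugged in instead.

## Training sets

Within-family (homologous) and one-shared-family (common-partner
analogous) pairs are positive when **iiRMSD < 8 Å** (strict);
common-partner pairs restrict the iiRMSD to the scenario aligning the
shared-family subunits, the only structurally meaningful pairing.
Native–decoy and four-distinct-family native–native pairs are negative
when **15 Å < iiRMSD < 25 Å** (both strict; the upper bound discards
gross alignment failures). Similarity-value distributions are compared
with the Bhattacharyya-coefficient distance d = √(1 − Σᵢ√(pᵢqᵢ)) on
**50 equal bins over [0, 30] Å**, out-of-range values clipped into the
end bins.

## Feature encoding and the SVM similarity

Each interface maps to 53 numbers: the contact-pair count; 28
class-pair contact frequencies over the seven physicochemical classes
(aliphatic, aromatic, positive, negative, small, hydrophobic, polar —
a multi-class contact increments every matching bin before
normalisation); interface ASA (sum of the two per-site means of
per-residue Shrake–Rupley SASA on the isolated subunit, probe 1.4 Å,
960 sphere points, element radii C 1.70 / N 1.55 / O 1.52 / S 1.80 /
H 1.20 Å — the sample sphere is anchored to a structure-intrinsic PCA
frame so SASA is exactly rigid-motion invariant); planarity (RMS
deviation of interface atoms from the least-squares plane, √λ_min of
the atom covariance); mean CX protrusion (10 Å sphere, 20.1 Å³ mean
atomic volume, clamped at 0); mean Fauchère–Pliska hydrophobicity; and
20 hot-spot residue-type frequencies (alphabetical three-letter
order). Feature 1 counts contact *pairs* |C|, the reading consistent
with the published feature-value ranges.

Hot spots use an empirical alanine-scanning stand-in (the original
MM-PBSA protocol is not reproducible from its description): a contact
residue is a hot spot when its side-chain heavy atoms beyond Cβ make
at least 8 weighted inter-subunit heavy-atom contacts within 5 Å,
opposite-charge N/O pairs within 4 Å counting double; ALA/GLY are
never hot spots. Thresholds are config-exposed.

Two interfaces combine into a 106-vector: indices 2–53 of the first,
then of the second, then |Δ contact count| and |Δ ASA| (positions 105,
106). The interface with more contacts goes first (ties: larger ASA,
then id), making the encoding — and hence δ and the distance —
symmetric by construction.

A soft-margin SVM (C = 1) on min–max-scaled pair vectors defines the
similarity δ as the kernel decision value; the distance is
δ_max − δ, floored at 0, with δ_max the maximum decision value over
the training pairs. The RBF γ defaults to the variance-adaptive
"scale" heuristic 1/(106·Var[X]) rather than a fixed 1/106: after
min–max scaling the feature variance is ≈ 0.05–0.1, and γ = 1/106
yields a nearly linear, badly underfit kernel. Model selection
(γ ∈ scale·{½,1,2,4,8}, C ∈ {1,10}) by leave-one-out accuracy on the
training pairs picks the final kernel. Scaling is re-fit inside every
cross-validation fold; the held-out pair never touches the scaler.
Feature ranking follows the recursive-elimination protocol with a
linear kernel: drop the smallest-|w| feature (ties drop the larger
id), retrain, rank by reverse elimination order.

The model serialises to JSON (support vectors, dual coefficients,
intercept, scaling, kernel, δ_max); the decision function is always
evaluated from those arrays, so a reloaded model reproduces decision
values bit-for-bit.

Two models are trained, mirroring the published protocol: the
native–decoy model (positives vs native–decoy negatives) carries the
headline cross-validation numbers; the model that adds native–native
negatives is the one used for clustering and retrieval, because a
model that has only seen decoy negatives provably fails to separate
structurally unrelated *native* pairs. For that clustering model,
cross-validated pair accuracy is nearly flat across usable kernels and
says nothing about how well the induced *distance* resolves corpus
structure, so its kernel is chosen by internal cluster validity:
among kernels within 0.1 of the best leave-one-out accuracy, the one
whose K-medoid clustering (K from the silhouette knee) attains the
highest mean silhouette wins, ties toward the smoother kernel. The
sharper kernels this favours keep the decision value informative for
out-of-distribution (cross-family) pairs instead of saturating.

## Hierarchy

A-level classes come from K-medoid (PAM: seeded medoid init,
assign-to-nearest, greedy swaps to convergence, best of 5 restarts) on
the all-against-all SVM distance matrix; K is the knee (maximum
perpendicular distance to the endpoint chord, ties to smaller K;
argmax silhouette available) of the mean-silhouette curve over the K
grid (default 2–10; singleton clusters contribute silhouette 0).
Within an A class, C classes are the connected components of the
share-a-family graph (transitive closure — the only reading that
yields a partition); within a C class, H classes group identical
unordered family pairs. Interfaces with missing labels form singleton
C/H classes.

## Retrieval

The M-Tree uses node capacity 8, promotion of the entry pair
minimising the larger covering radius, and generalised-hyperplane
partitioning. k-NN search is branch-and-bound; because the SVM
distance is only empirically metric, pruning subtracts a slack ε, set
to the corpus's largest observed triangle excess (0 when the corpus is
metric). Ties are broken by object id, and equal-distance candidates
are never pruned, so results match a linear scan exactly. The
retrieval error of a query is the excess iiRMSD of the retrieved
interface over the best achievable in the corpus — the only
Å-consistent reconstruction of the published definition, whose formula
figure did not survive reproduction.

## Synthetic corpus

The generator emulates the study conditions offline. A *family* is a
randomized α-helical bundle fold: ideal helix geometry (3.8 Å Cα
spacing), 12–18 residues per helix, row or 2-D lattice packing,
randomized spacing (8.5–13.5 Å), tilts (±0.15 rad), phases, staggers
and a smooth low-frequency deformation — folds from different seeds
superpose at > 5 Å Cα RMSD, while family members (Gaussian coordinate
noise, default σ = 1 Å; 10 % residue mutations, class-preserving with
probability 0.7) stay well inside the 8 Å positive regime. Each
residue carries backbone N/CA/C/O, a Cβ and a single side-chain
centroid pseudo-atom at a residue-size-dependent distance. Complexes
dock face-to-face: the flattest faces (smallest principal axes) meet,
the mobile subunit settles by greedy contact-maximising rocking, and
the closest atoms come to rest at 2.8–3.6 Å — the hydrogen-bond to
van-der-Waals contact range; this is deliberately tighter than a pure
vdW gap because the coarse side-chain centroids cannot interdigitate
the way full-atom side chains do, and a looser gap yields unrealistic
point contacts. Interfaces have ≥ 15 contact pairs (resampled
otherwise). Decoys detach subunit B, rotate it 60–180°, displace it
laterally up to 30 Å and slide it back to a 3.0–4.5 Å contact gap
without clashes (< 2.2 Å rejected) — deterministic per seed.

The default corpus is 5 families × 4 members with 10 decoys per
family at 130 residues per subunit. Subunit size matters more than it
looks: the published Å thresholds (8/15/25) are calibrated to
full-size protein domains, and at half scale unrelated native pairs
score 5–15 Å instead of 15–25, emptying the native–native negative
window. 130 residues restores the thresholds' intended meaning.

What the generator does not emulate: β-structure, loops, side-chain
packing and chemistry (so hot spots are rare and ASA/protrusion are
coarse), crystallographic artefacts, and realistic family-size
distributions (real corpora are dominated by singleton families).
Passing tests show the pipeline recovers planted structure under
idealised geometry; they do not certify accuracy on real PDB corpora.

## Numerical choices

RMSD values below 1e−9 Å report as 0. Kabsch uses SVD with a
determinant correction (never a reflection). The silhouette of
all-identical points is 0 by convention. K-medoid objective ties are
broken by candidate order, making runs reproducible for a given seed.
The M-Tree never prunes at equality. LOOCV requires ≥ 20 pairs,
training ≥ 10 per class. Histograms clip rather than drop outliers.

## Known limitations

- The built-in aligner is sequence-seeded; for remote homologs with
  conserved structure but scrambled sequence order it relies entirely
  on the fragment fallback, which is weaker than a true
  sequence-order-independent aligner. The provider interface accepts
  an external aligner for that case.
- On small, replicate-heavy corpora the SVM distance violates the
  triangle inequality at a few percent of triples: homolog pairs sit
  at distance ≈ 0 while their distances to a third interface differ,
  which is exactly a triangle violation. Large diverse corpora
  (mostly singleton families, as in the published survey) smooth the
  value distribution and the violation rate falls well below 1 %;
  retrieval remains exact regardless through the pruning slack.
- Reported cross-validation accuracies on the synthetic corpus are
  near-perfect because the decoy negatives are geometrically much
  easier than real dissimilar biological interfaces; they validate
  the machinery, not the published accuracy figures, which depend on
  the original curated corpus.
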