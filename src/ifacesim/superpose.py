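"""Rigid superposition and structure-based interface similarity measures.

Two measures compare a pair of protein-protein interactions:

* **iiRMSD** (interaction-interface RMSD) superposes whole subunits.
  For each of the four subunit pairings (A1-B1, A1-B2, A2-B1, A2-B2) the
  paired subunits are structurally aligned; the Calpha RMSD over the
  corresponded binding-site residues of the aligned pair is averaged
  with the Calpha RMSD of the *remaining* pair of binding sites under
  the same transform, and the smallest of the four averages is
  reported.  The second term is what penalises a different binding mode
  even when the subunits themselves are similar.
* **siRMSD** (superposed-interface RMSD) aligns only the interface
  residues (both binding sites pooled, site identity preserved) and
  reports the Calpha RMSD over the corresponded residues.

Structural alignment is provided by a built-in sequence-seeded
iterative-closest-Calpha aligner with a fragment-superposition fallback
for sequence-dissimilar pairs; any aligner producing a residue
correspondence plus a rigid transform can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .structure_io import (
    Interaction,
    Interface,
    ResidueId,
    Subunit,
    build_interface,
)

#: values below this (Angstrom) are reported as exactly 0
_ZERO_SNAP = 1e-9

#: refinement pairing radius (Angstrom)
_PAIR_RADIUS = 5.0
_MAX_REFINE_ITERS = 20
_FRAGMENT_LEN = 12
_FRAGMENT_STRIDE = 3


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class AlignmentResult:
    """One-to-one residue correspondence plus the superposing transform.

    ``transform`` maps coordinates of the second structure onto the
    first; ``aligned_rmsd`` is the Calpha RMSD over the correspondence.
    """

    correspondence: list[tuple[ResidueId, ResidueId]]
    transform: RigidTransform
    aligned_rmsd: float

    @property
    def ok(self) -> bool:
        return True


@dataclass
class AlignmentFailure:
    reason: str

    @property
    def ok(self) -> bool:
        return False


def kabsch_superpose(
    points_a: np.ndarray, points_b: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of B onto A (Kabsch, via SVD).

    Returns the transform minimising RMSD(R b + t, a) and that minimum.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    H = b0.T @ a0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    resid = a0 - b0 @ R.T
    msd = float(np.mean(np.sum(resid * resid, axis=1)))
    rmsd = float(np.sqrt(max(msd, 0.0)))
    if rmsd < _ZERO_SNAP:
        rmsd = 0.0
    return RigidTransform(R, t), rmsd


# ---------------------------------------------------------------------------
# Built-in alignment provider

def _identity_nw(seq_a: Sequence[str], seq_b: Sequence[str]) -> list[tuple[int, int]]:
    """Global alignment of residue-type strings with identity scoring.

    Match 1, mismatch 0, gap -0.5.  Returns aligned index pairs.
    """
    n, m = len(seq_a), len(seq_b)
    gap = -0.5
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        match = score[i - 1, :-1] + (np.array([1.0 if seq_a[i - 1] == b else 0.0 for b in seq_b]))
        for j in range(1, m + 1):
            diag = match[j - 1]
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(diag, up, left)
            score[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _refine(
    ca_a: np.ndarray,
    ca_b: np.ndarray,
    seed_pairs: list[tuple[int, int]],
    blocks_a: np.ndarray | None = None,
    blocks_b: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], RigidTransform, float] | None:
    """Iterative Kabsch refinement with correspondence re-estimation.

    After each superposition, Calpha atoms are re-paired by mutual
    nearest neighbour within 5 Angstrom (restricted to matching block
    labels when given); iterate to convergence, at most 20 rounds.
    """
    pairs = seed_pairs
    if len(pairs) < 3:
        return None
    transform, rmsd = kabsch_superpose(
        ca_a[[i for i, _ in pairs]], ca_b[[j for _, j in pairs]]
    )
    for _ in range(_MAX_REFINE_ITERS):
        moved = transform.apply(ca_b)
        new_pairs = _mutual_nn_pairs(ca_a, moved, blocks_a, blocks_b)
        if len(new_pairs) < 3:
            break
        if new_pairs == pairs:
            break
        pairs = new_pairs
        transform, rmsd = kabsch_superpose(
            ca_a[[i for i, _ in pairs]], ca_b[[j for _, j in pairs]]
        )
    return pairs, transform, rmsd


def _mutual_nn_pairs(
    ca_a: np.ndarray,
    moved_b: np.ndarray,
    blocks_a: np.ndarray | None,
    blocks_b: np.ndarray | None,
) -> list[tuple[int, int]]:
    tree_a = cKDTree(ca_a)
    tree_b = cKDTree(moved_b)
    d_ab, nn_ab = tree_b.query(ca_a, k=1, distance_upper_bound=_PAIR_RADIUS)
    d_ba, nn_ba = tree_a.query(moved_b, k=1, distance_upper_bound=_PAIR_RADIUS)
    pairs = []
    for i in range(len(ca_a)):
        j = nn_ab[i]
        if j >= len(moved_b):
            continue
        if nn_ba[j] != i:
            continue
        if blocks_a is not None and blocks_a[i] != blocks_b[j]:
            continue
        pairs.append((i, int(j)))
    return pairs


def _align_ca(
    ca_a: np.ndarray,
    seq_a: Sequence[str],
    ca_b: np.ndarray,
    seq_b: Sequence[str],
    min_coverage: float,
    blocks_a: np.ndarray | None = None,
    blocks_b: np.ndarray | None = None,
    try_fragments: bool = True,
) -> tuple[list[tuple[int, int]], RigidTransform, float] | None:
    """Core Calpha aligner: sequence seeding, fragment fallback, refinement."""
    need = max(3, int(np.ceil(min_coverage * min(len(ca_a), len(ca_b)))))
    best = None

    def consider(result):
        nonlocal best
        if result is None:
            return
        pairs, transform, rmsd = result
        if best is None or (len(pairs), -rmsd) > (len(best[0]), -best[2]):
            best = result

    seed = _identity_nw(seq_a, seq_b)
    if blocks_a is not None:
        seed = [(i, j) for i, j in seed if blocks_a[i] == blocks_b[j]]
    consider(_refine(ca_a, ca_b, seed, blocks_a, blocks_b))

    if (best is None or len(best[0]) < need) and try_fragments:
        L = _FRAGMENT_LEN
        if len(ca_a) >= L and len(ca_b) >= L:
            # pre-screen all fragment pairs by their own Kabsch RMSD and
            # refine only the best-superposing seeds
            seeds = []
            for ia in range(0, len(ca_a) - L + 1, _FRAGMENT_STRIDE):
                for ib in range(0, len(ca_b) - L + 1, _FRAGMENT_STRIDE):
                    frag = [(ia + k, ib + k) for k in range(L)]
                    if blocks_a is not None and any(
                        blocks_a[i] != blocks_b[j] for i, j in frag
                    ):
                        continue
                    _, frag_rmsd = kabsch_superpose(ca_a[ia:ia + L], ca_b[ib:ib + L])
                    seeds.append((frag_rmsd, frag))
            seeds.sort(key=lambda x: x[0])
            for _, frag in seeds[:12]:
                consider(_refine(ca_a, ca_b, frag, blocks_a, blocks_b))
                if best is not None and len(best[0]) >= min(len(ca_a), len(ca_b)):
                    break
    if best is None or len(best[0]) < need:
        return None
    return best


def align_subunits(
    a: Subunit, b: Subunit, min_coverage: float = 0.6
) -> AlignmentResult | AlignmentFailure:
    """Structurally align two subunits (Calpha level).

    Succeeds when the refined correspondence covers at least
    ``min_coverage`` of the shorter subunit's Calpha count.
    """
    rids_a, ca_a = a.ca_array()
    rids_b, ca_b = b.ca_array()
    if len(ca_a) < 8 or len(ca_b) < 8:
        return AlignmentFailure("fewer than 8 Calpha atoms in a subunit")
    seq_a = [a.residue(r).res_type for r in rids_a]
    seq_b = [b.residue(r).res_type for r in rids_b]
    result = _align_ca(ca_a, seq_a, ca_b, seq_b, min_coverage)
    if result is None:
        return AlignmentFailure(
            f"alignment coverage below {min_coverage:.0%} of the shorter subunit"
        )
    pairs, transform, rmsd = result
    corr = [(rids_a[i], rids_b[j]) for i, j in pairs]
    return AlignmentResult(corr, transform, rmsd)


class CachedAligner:
    """Memoizing wrapper around :func:`align_subunits` for corpus-scale
    pipelines, where the same subunit pairs recur across the four
    iiRMSD scenarios and across interface pairs.  Keyed by object
    identity; hold the corpus alive while using it."""

    def __init__(self, aligner: Callable = align_subunits):
        self._aligner = aligner
        self._cache: dict[tuple[int, int, float], AlignmentResult | AlignmentFailure] = {}

    def __call__(self, a: Subunit, b: Subunit, min_coverage: float = 0.6):
        key = (id(a), id(b), min_coverage)
        if key not in self._cache:
            self._cache[key] = self._aligner(a, b, min_coverage=min_coverage)
        return self._cache[key]


# ---------------------------------------------------------------------------
# iiRMSD

_SCENARIOS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class ScenarioReport:
    pairing: str
    value: float | None
    rmsd_aligned: float | None = None
    rmsd_remaining: float | None = None
    n_skipped: int = 0
    failure: str | None = None


@dataclass
class IIRMSDResult:
    value: float | None
    scenario: str | None
    reports: list[ScenarioReport] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.value is not None


def _site_ca(sub: Subunit, site_residues: frozenset[ResidueId]):
    rids, coords = [], []
    for r in sub.residues:
        if r.rid in site_residues and r.ca is not None:
            rids.append(r.rid)
            coords.append(r.ca)
    return rids, np.asarray(coords, float).reshape(-1, 3)


def _site_rmsd_under_transform(
    sub_a: Subunit,
    site_a: frozenset[ResidueId],
    sub_b: Subunit,
    site_b: frozenset[ResidueId],
    corr: dict[ResidueId, ResidueId],
    transform: RigidTransform,
) -> tuple[float | None, int]:
    """Calpha RMSD over corresponded binding-site residues; returns
    (rmsd or None, number of site residues without a correspondence).

    A correspondence pair contributes when either of its residues is a
    binding-site residue, so a changed binding mode (the partner site
    moving to different residues) registers as a large RMSD instead of
    shrinking the comparison to the overlap.
    """
    pa, pb, skipped = [], [], 0
    corr_b = set(corr.values())
    inv = {b: a for a, b in corr.items()}
    for r in sub_a.residues:
        mate = corr.get(r.rid)
        if r.rid not in site_a and (mate is None or mate not in site_b):
            continue
        if r.ca is None:
            continue
        if mate is None:
            skipped += 1
            continue
        mate_res = sub_b.residue(mate)
        if mate_res.ca is None:
            skipped += 1
            continue
        pa.append(r.ca)
        pb.append(mate_res.ca)
    skipped += sum(1 for rid in site_b if rid not in corr_b)
    if not pa:
        return None, skipped
    pa = np.asarray(pa)
    pb = transform.apply(np.asarray(pb))
    rmsd = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    return (0.0 if rmsd < _ZERO_SNAP else rmsd), skipped


def _geometric_correspondence(
    sub_a: Subunit,
    site_a: frozenset[ResidueId],
    sub_b: Subunit,
    site_b: frozenset[ResidueId],
    transform: RigidTransform,
) -> dict[ResidueId, ResidueId]:
    """Minimum-cost one-to-one pairing of binding-site Calpha atoms
    after applying the scenario transform (used when the remaining
    subunits cannot be structurally aligned)."""
    rids_a, ca_a = _site_ca(sub_a, site_a)
    rids_b, ca_b = _site_ca(sub_b, site_b)
    if len(rids_a) == 0 or len(rids_b) == 0:
        return {}
    moved = transform.apply(ca_b)
    cost = np.linalg.norm(ca_a[:, None, :] - moved[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {rids_a[i]: rids_b[j] for i, j in zip(rows, cols)}


def iirmsd(
    inter1: Interaction,
    inter2: Interaction,
    iface1: Interface | None = None,
    iface2: Interface | None = None,
    cutoff: float = 6.0,
    min_coverage: float = 0.6,
    scenarios: Sequence[tuple[int, int]] | None = None,
    aligner: Callable[..., AlignmentResult | AlignmentFailure] = align_subunits,
) -> IIRMSDResult:
    """Interaction-interface RMSD between two interactions.

    The minimum over the four subunit-pairing scenarios of the mean of
    (i) the binding-site Calpha RMSD of the aligned subunit pair and
    (ii) the binding-site Calpha RMSD of the remaining pair under the
    same transform.  Scenarios whose alignment fails are skipped; if
    all fail the result is undefined and carries the reasons.
    ``scenarios`` restricts the pairings considered (used for
    common-partner pairs where only one subunit pair is alignable).
    """
    if iface1 is None:
        iface1 = build_interface(inter1, cutoff)
    if iface2 is None:
        iface2 = build_interface(inter2, cutoff)
    subs1 = (inter1.subunit_a, inter1.subunit_b)
    subs2 = (inter2.subunit_a, inter2.subunit_b)
    sites1 = {inter1.subunit_a.id: iface1.site_a.residues, inter1.subunit_b.id: iface1.site_b.residues}
    sites2 = {inter2.subunit_a.id: iface2.site_a.residues, inter2.subunit_b.id: iface2.site_b.residues}

    reports: list[ScenarioReport] = []
    best: tuple[float, str] | None = None
    for (i, j) in (scenarios if scenarios is not None else _SCENARIOS):
        name = f"A{i + 1}-B{j + 1}"
        a_al, a_rem = subs1[i], subs1[1 - i]
        b_al, b_rem = subs2[j], subs2[1 - j]
        aln = aligner(a_al, b_al, min_coverage=min_coverage)
        if not aln.ok:
            reports.append(ScenarioReport(name, None, failure=aln.reason))
            continue
        corr = dict(aln.correspondence)
        rmsd1, sk1 = _site_rmsd_under_transform(
            a_al, sites1[a_al.id], b_al, sites2[b_al.id], corr, aln.transform
        )
        if rmsd1 is None:
            reports.append(
                ScenarioReport(name, None, failure="no corresponded binding-site residues in aligned pair")
            )
            continue
        rem_aln = aligner(a_rem, b_rem, min_coverage=min_coverage)
        if rem_aln.ok:
            rem_corr = dict(rem_aln.correspondence)
        else:
            rem_corr = _geometric_correspondence(
                a_rem, sites1[a_rem.id], b_rem, sites2[b_rem.id], aln.transform
            )
        rmsd2, sk2 = _site_rmsd_under_transform(
            a_rem, sites1[a_rem.id], b_rem, sites2[b_rem.id], rem_corr, aln.transform
        )
        if rmsd2 is None:
            reports.append(
                ScenarioReport(name, None, failure="no corresponded binding-site residues in remaining pair")
            )
            continue
        avg = 0.5 * (rmsd1 + rmsd2)
        if avg < _ZERO_SNAP:
            avg = 0.0
        reports.append(ScenarioReport(name, avg, rmsd1, rmsd2, sk1 + sk2))
        if best is None or avg < best[0]:
            best = (avg, name)
    if best is None:
        return IIRMSDResult(None, None, reports)
    return IIRMSDResult(best[0], best[1], reports)


# ---------------------------------------------------------------------------
# siRMSD

def sirmsd(
    inter1: Interaction,
    inter2: Interaction,
    iface1: Interface | None = None,
    iface2: Interface | None = None,
    cutoff: float = 6.0,
    min_coverage: float = 0.5,
) -> float | None:
    """Superposed-interface RMSD: align the pooled interface residues
    only (site identity preserved) and report the Calpha RMSD over the
    correspondence; best of the two site-to-site orientations.
    Returns None when neither orientation aligns."""
    if iface1 is None:
        iface1 = build_interface(inter1, cutoff)
    if iface2 is None:
        iface2 = build_interface(inter2, cutoff)

    def pooled(inter, iface):
        rids, coords, seq, blocks = [], [], [], []
        for block, (sub, site) in enumerate(
            ((inter.subunit_a, iface.site_a.residues), (inter.subunit_b, iface.site_b.residues))
        ):
            srids, sca = _site_ca(sub, site)
            rids.extend(srids)
            coords.extend(sca)
            seq.extend(sub.residue(r).res_type for r in srids)
            blocks.extend([block] * len(srids))
        return rids, np.asarray(coords, float).reshape(-1, 3), seq, np.asarray(blocks)

    rids1, ca1, seq1, blocks1 = pooled(inter1, iface1)
    _, ca2, seq2, blocks2 = pooled(inter2, iface2)
    if np.sum(blocks1 == 0) < 4 or np.sum(blocks1 == 1) < 4:
        return None
    if np.sum(blocks2 == 0) < 4 or np.sum(blocks2 == 1) < 4:
        return None

    best: float | None = None
    for flip in (False, True):
        b2 = 1 - blocks2 if flip else blocks2
        result = _align_ca(ca1, seq1, ca2, seq2, min_coverage, blocks1, b2)
        if result is None:
            continue
        _, _, rmsd = result
        if best is None or rmsd < best:
            best = rmsd
    if best is not None and best < _ZERO_SNAP:
        best = 0.0
    return best


# ---------------------------------------------------------------------------
# Decoy generation

class DecoyError(Exception):
    """Decoy placement attempts exhausted."""


def _min_interatomic(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    tree = cKDTree(coords_a)
    d, _ = tree.query(coords_b, k=1)
    return float(np.min(d))


def _random_rotation(rng: np.random.Generator, lo_deg: float, hi_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(lo_deg, hi_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_decoy(
    inter: Interaction,
    seed: int,
    rot_range: tuple[float, float] = (60.0, 180.0),
    trans_range: float = 30.0,
    gap_window: tuple[float, float] = (3.0, 4.5),
    max_attempts: int = 100,
) -> Interaction:
    """Alternative-binding-mode decoy by seeded rigid perturbation.

    Subunit B is rotated about its centroid (angle sampled from
    ``rot_range`` degrees, random axis), translated laterally, then slid
    along the inter-centroid axis until the minimum inter-subunit atom
    distance falls in ``gap_window`` Angstrom, guaranteeing contact
    without steric clash.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    coords_a = inter.subunit_a.all_atoms()
    for _ in range(max_attempts):
        R = _random_rotation(rng, *rot_range)
        centroid_b = inter.subunit_b.all_atoms().mean(axis=0)
        lateral = rng.uniform(-trans_range, trans_range, size=3)
        # rotate about own centroid then shift laterally
        t = centroid_b - R @ centroid_b + lateral
        moved = inter.subunit_b.transformed(R, t)
        coords_b = moved.all_atoms()
        axis = coords_b.mean(axis=0) - coords_a.mean(axis=0)
        norm = np.linalg.norm(axis)
        if norm < 1e-6:
            continue
        axis = axis / norm
        target = 0.5 * (gap_window[0] + gap_window[1])

        def gap(s: float) -> float:
            return _min_interatomic(coords_a, coords_b + s * axis)

        s_lo, s_hi = -norm, 200.0
        if gap(s_hi) < target:
            continue
        ok = True
        g_lo = gap(s_lo)
        if g_lo > target:  # slide inward further is impossible; skip
            ok = False
        if not ok:
            continue
        for _ in range(60):
            mid = 0.5 * (s_lo + s_hi)
            if gap(mid) < target:
                s_lo = mid
            else:
                s_hi = mid
        s = s_hi
        final_gap = gap(s)
        if not (gap_window[0] <= final_gap <= gap_window[1]):
            continue
        placed = inter.subunit_b.transformed(R, t + s * axis)
        if _min_interatomic(coords_a, placed.all_atoms()) < 2.2:
            continue
        return Interaction(inter.subunit_a, placed, id=f"{inter.id}~decoy{seed}")
    raise DecoyError(f"could not place decoy in {max_attempts} attempts (seed {seed})")
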