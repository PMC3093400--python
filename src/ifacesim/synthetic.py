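"""Synthetic protein-complex generator with planted ground truth.

Stands in for a curated corpus of experimentally solved complexes:
each *family* is an idealized alpha-helical-bundle fold (randomized
helix spacing, tilt, phase and a smooth low-frequency deformation make
folds from different seeds structurally distinct), each family member
is a noisy, partially mutated copy of the family's docked complex, and
decoys are rigid re-placements of one subunit.  Every pair relation
(homologous / unrelated / native-decoy) and the planted family
partition are recorded, so similarity measures, training-set filters,
clustering and retrieval can all be validated offline.

Geometry: Calpha atoms follow an ideal alpha helix (1.5 Angstrom rise,
100 degrees per residue, 2.3 Angstrom radius) so Calpha spacing is the
physical 3.8 Angstrom; each residue carries N, C, O backbone atoms, a
Cbeta, and one pseudo side-chain atom placed outward at a
residue-size-dependent distance (absent for GLY, Cbeta only for ALA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import (
    Atom,
    Interaction,
    Residue,
    STANDARD_RESIDUES,
    Subunit,
    build_interface,
    detect_contacts,
    write_pdb,
)
from .superpose import make_decoy
from .features import RESIDUE_CLASS_TABLE

#: distance of the pseudo side-chain centroid beyond Cbeta, Angstrom
#: (coarse, ordered by residue bulk); GLY/ALA handled separately
_SIDECHAIN_LEN = {
    "SER": 0.5, "CYS": 0.6, "THR": 0.7, "VAL": 0.7, "PRO": 0.6,
    "ASP": 0.9, "ASN": 0.9, "ILE": 1.1, "LEU": 1.1, "MET": 1.3,
    "GLU": 1.3, "GLN": 1.3, "HIS": 1.3, "LYS": 1.7, "PHE": 1.5,
    "ARG": 2.0, "TYR": 1.7, "TRP": 1.7,
}

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN_DEG = 100.0
_RES_PER_HELIX = 15


class PlacementError(Exception):
    """Docking placement attempts exhausted."""


@dataclass
class GeneratorSpec:
    """Study conditions for a synthetic corpus."""

    n_families: int = 5
    members_per_family: int = 4
    subunit_size: int = 130
    noise_sd: float = 1.0
    mutation_rate: float = 0.1
    n_decoys_per_family: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.members_per_family, self.subunit_size) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _residue_atoms(
    res_type: str, ca: np.ndarray, chain_dir: np.ndarray, normal: np.ndarray
) -> list[Atom]:
    """Backbone + coarse side chain around a Calpha position."""
    atoms = [
        Atom("N", "N", tuple(ca - 1.2 * chain_dir + 0.3 * normal)),
        Atom("CA", "C", tuple(ca)),
        Atom("C", "C", tuple(ca + 1.2 * chain_dir - 0.3 * normal)),
        Atom("O", "O", tuple(ca + 1.4 * chain_dir + 0.8 * normal)),
    ]
    if res_type != "GLY":
        cb = ca + 1.5 * normal
        atoms.append(Atom("CB", "C", tuple(cb)))
        ext = _SIDECHAIN_LEN.get(res_type)
        if ext is not None:
            element = "N" if res_type in ("ARG", "LYS", "HIS") else (
                "O" if res_type in ("ASP", "GLU") else "C"
            )
            atoms.append(Atom("SC", element, tuple(cb + ext * normal)))
    return atoms


def make_family_template(seed: int, size: int = 30, chain_id: str = "A") -> Subunit:
    """Idealized helical-bundle subunit; distinct fold per seed.

    Helix spacing, tilt, phase, order and a smooth global deformation
    are all drawn from the seed, so templates from different seeds
    superpose with Calpha RMSD well above the family noise level.
    """
    if size < 20:
        raise ValueError("template needs at least 20 residues")
    rng = np.random.default_rng(seed)
    res_per_helix = int(rng.integers(12, 19))  # fold-level diversity
    n_helices = int(np.ceil(size / res_per_helix))
    spacing = rng.uniform(8.5, 13.5)
    seq = [STANDARD_RESIDUES[i] for i in rng.integers(0, 20, size=size)]
    # bundle arrangement: helices in a row, or packed on a 2-D lattice
    if n_helices >= 3 and rng.random() < 0.5:
        lattice = [
            np.array([(h % 2) * spacing, (h // 2) * rng.uniform(8.5, 13.5), 0.0])
            for h in range(n_helices)
        ]
    else:
        lattice = [np.array([h * spacing, 0.0, 0.0]) for h in range(n_helices)]

    residues: list[Residue] = []
    res_idx = 0
    for h in range(n_helices):
        n_res = min(res_per_helix, size - h * res_per_helix)
        phase = rng.uniform(0, 2 * np.pi)
        tilt = rng.uniform(-0.15, 0.15, size=2)  # radians, about x and y
        antiparallel = bool(rng.random() < 0.5) if h > 0 else False
        offset = lattice[h] + np.array([0.0, rng.uniform(-3, 3), rng.uniform(-6, 6)])
        Rx = _rot_x(tilt[0])
        Ry = _rot_y(tilt[1])
        frame = Rx @ Ry
        for k in range(n_res):
            ang = phase + np.deg2rad(_HELIX_TURN_DEG) * k
            z = _HELIX_RISE * k
            if antiparallel:
                z = _HELIX_RISE * (n_res - 1 - k)
            local = np.array([_HELIX_RADIUS * np.cos(ang), _HELIX_RADIUS * np.sin(ang), z])
            ca = frame @ local + offset
            axis_point = frame @ np.array([0.0, 0.0, local[2]]) + offset
            normal = ca - axis_point
            normal /= np.linalg.norm(normal)
            chain_dir = frame @ np.array([0.0, 0.0, -1.0 if antiparallel else 1.0])
            res_idx += 1
            residues.append(
                Residue(chain_id, res_idx, "", seq[res_idx - 1],
                        _residue_atoms(seq[res_idx - 1], ca, chain_dir, normal))
            )
    # smooth low-frequency deformation: distinguishes folds without
    # breaking local helix geometry
    amp = rng.uniform(0.5, 1.0)
    freq = rng.uniform(0.05, 0.12)
    phase3 = rng.uniform(0, 2 * np.pi, size=3)
    deformed = []
    for r in residues:
        s = r.seq_id
        shift = amp * np.array([
            np.sin(freq * s * 2 * np.pi + phase3[0]),
            np.sin(freq * s * 2 * np.pi + phase3[1]),
            np.cos(freq * s * 2 * np.pi + phase3[2]),
        ])
        atoms = [Atom(a.name, a.element, tuple(a.xyz + shift)) for a in r.atoms]
        deformed.append(Residue(r.chain_id, r.seq_id, r.icode, r.res_type, atoms))
    return Subunit(chain_id, deformed)


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis orthogonal to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        return _axis_rotation(axis, np.pi)
    axis = np.cross(u, v)
    angle = np.arccos(c)
    return _axis_rotation(axis, angle)


def make_complex(
    template_a: Subunit,
    template_b: Subunit,
    seed: int,
    min_contacts: int = 15,
    max_tries: int = 50,
) -> Interaction:
    """Dock subunit B face-to-face against A.

    The flattest faces of the two bundles (smallest principal axes) are
    brought together — randomly spun about the docking axis and tilted
    — and B is slid in until the closest heavy-atom pair sits at
    2.8-3.6 Angstrom (the hydrogen-bond-to-van-der-Waals contact
    range); orientations are resampled until the interface has at
    least ``min_contacts`` residue contact pairs.
    """
    rng = np.random.default_rng(seed)
    coords_a = template_a.all_atoms()
    centroid_a = coords_a.mean(axis=0)
    from scipy.spatial import cKDTree

    tree_a = cKDTree(coords_a)

    def _smallest_axis(coords: np.ndarray) -> np.ndarray:
        c = coords - coords.mean(axis=0)
        w, v = np.linalg.eigh(c.T @ c)
        return v[:, 0]  # smallest-variance direction = flat-face normal

    axis_a = _smallest_axis(coords_a)
    raw_b = template_b.all_atoms()
    centroid_b = raw_b.mean(axis=0)
    axis_b = _smallest_axis(raw_b)

    def _slide_to_gap(R: np.ndarray, direction: np.ndarray, target_gap: float):
        """Park B far out along ``direction`` and slide in until the
        closest inter-subunit atom pair sits at ``target_gap``."""
        base_t = centroid_a - R @ centroid_b + 100.0 * direction
        coords_b = raw_b @ R.T + base_t

        def gap(s: float) -> float:
            d, _ = tree_a.query(coords_b - s * direction, k=1)
            return float(np.min(d))

        lo, hi = 0.0, 100.0
        if gap(lo) < target_gap:
            return None
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if gap(mid) > target_gap:
                lo = mid
            else:
                hi = mid
        return R, base_t - lo * direction

    def _n_contacts(R: np.ndarray, t: np.ndarray) -> int:
        placed = template_b.transformed(R, t)
        return len(detect_contacts(template_a, placed))

    for _ in range(max_tries):
        direction = axis_a * (1.0 if rng.random() < 0.5 else -1.0)
        # tilt the docking direction slightly for pose diversity
        direction = direction + rng.normal(scale=0.15, size=3)
        direction /= np.linalg.norm(direction)
        # rotate B so its flat face points back along the docking axis,
        # then spin it randomly about that axis
        R_face = _rotation_between(axis_b, -direction)
        spin = _axis_rotation(direction, rng.uniform(0, 2 * np.pi))
        R = spin @ R_face
        target_gap = rng.uniform(2.8, 3.6)
        pose = _slide_to_gap(R, direction, target_gap)
        if pose is None:
            continue
        best_R, best_t = pose
        best_n = _n_contacts(best_R, best_t)
        # settle: greedy corrective rocking about axes perpendicular to
        # the docking direction, re-sliding after each candidate, so the
        # faces come to rest flush rather than touching at one bump
        perp1 = np.cross(direction, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp1) < 1e-6:
            perp1 = np.cross(direction, [0.0, 1.0, 0.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(direction, perp1)
        for _round in range(12):
            improved = False
            for axis, degs in (
                (perp1, (-8.0, -4.0, -2.0, 2.0, 4.0, 8.0)),
                (perp2, (-8.0, -4.0, -2.0, 2.0, 4.0, 8.0)),
                (direction, (-15.0, -8.0, 8.0, 15.0)),  # spin: groove alignment
            ):
                for deg in degs:
                    Rc = _axis_rotation(axis, np.deg2rad(deg)) @ best_R
                    cand = _slide_to_gap(Rc, direction, target_gap)
                    if cand is None:
                        continue
                    n = _n_contacts(*cand)
                    if n > best_n:
                        best_R, best_t = cand
                        best_n = n
                        improved = True
            if not improved:
                break
        placed = template_b.transformed(best_R, best_t)
        if _min_dist(coords_a, placed.all_atoms()) < 2.5:
            continue
        if best_n >= min_contacts:
            return Interaction(template_a, placed)
    raise PlacementError(f"no placement with >= {min_contacts} contacts in {max_tries} tries")


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(a).query(b, k=1)
    return float(np.min(d))


def _mutate(res_type: str, rng: np.random.Generator) -> str:
    """Re-type a residue; class-preserving with probability 0.7."""
    if rng.random() < 0.7:
        classes = RESIDUE_CLASS_TABLE.classes_of(res_type)
        if classes:
            cls = classes[rng.integers(0, len(classes))]
            members = [r for r in RESIDUE_CLASS_TABLE.members_of(cls) if r != res_type]
            if members:
                return members[rng.integers(0, len(members))]
    others = [r for r in STANDARD_RESIDUES if r != res_type]
    return others[rng.integers(0, len(others))]


def make_homolog_pair(
    complex_: Interaction,
    noise_sd: float,
    mutation_rate: float,
    seed: int,
) -> Interaction:
    """A homologous copy: Gaussian coordinate noise plus a fraction of
    class-preserving residue mutations; binding mode and family labels
    unchanged; the identity residue mapping is the ground-truth
    correspondence."""
    rng = np.random.default_rng(seed)

    def perturb(sub: Subunit) -> Subunit:
        new_res = []
        for r in sub.residues:
            res_type = r.res_type
            if rng.random() < mutation_rate:
                res_type = _mutate(res_type, rng)
            atoms = [
                Atom(a.name, a.element, tuple(a.xyz + rng.normal(0.0, noise_sd, size=3)))
                for a in r.atoms
            ]
            new_res.append(Residue(r.chain_id, r.seq_id, r.icode, res_type, atoms))
        return Subunit(sub.id, new_res, sub.family_label)

    return Interaction(perturb(complex_.subunit_a), perturb(complex_.subunit_b), id=complex_.id)


# ---------------------------------------------------------------------------
# Corpus

@dataclass
class SyntheticCorpus:
    natives: list[Interaction]
    decoys: list[tuple[str, Interaction]]  # (native id, decoy interaction)
    family_labels: dict[str, str]  # subunit id -> family label
    planted: dict[str, int]  # native id -> family index
    truth_pairs: pd.DataFrame = field(repr=False)  # id_1, id_2, relation

    @property
    def all_interactions(self) -> list[Interaction]:
        return self.natives + [d for _, d in self.decoys]


def _relabel(inter: Interaction, cid: str, fam_a: str, fam_b: str) -> Interaction:
    sa = Subunit(f"{cid}:A", inter.subunit_a.residues, fam_a)
    sb = Subunit(f"{cid}:B", inter.subunit_b.residues, fam_b)
    return Interaction(sa, sb, id=cid)


def make_corpus(spec: GeneratorSpec) -> SyntheticCorpus:
    """Families of homologous complexes, cross-family unrelated
    complexes, and rigid-perturbation decoys, with full truth tables."""
    rng = np.random.default_rng(spec.seed)
    natives: list[Interaction] = []
    planted: dict[str, int] = {}
    labels: dict[str, str] = {}
    decoys: list[tuple[str, Interaction]] = []

    for f in range(spec.n_families):
        seed_a = int(rng.integers(0, 2**31 - 1))
        seed_b = int(rng.integers(0, 2**31 - 1))
        ta = make_family_template(seed_a, spec.subunit_size, chain_id="A")
        tb = make_family_template(seed_b, spec.subunit_size, chain_id="B")
        base = None
        for attempt in range(10):
            try:
                base = make_complex(ta, tb, seed=int(rng.integers(0, 2**31 - 1)))
                break
            except PlacementError:
                continue
        if base is None:
            raise PlacementError(f"family {f}: docking failed")
        fam_a, fam_b = f"SF{2 * f}", f"SF{2 * f + 1}"
        for m in range(spec.members_per_family):
            cid = f"F{f}m{m}"
            if m == 0:
                member = base
            else:
                member = make_homolog_pair(
                    base, spec.noise_sd, spec.mutation_rate,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            member = _relabel(member, cid, fam_a, fam_b)
            natives.append(member)
            planted[cid] = f
            labels[member.subunit_a.id] = fam_a
            labels[member.subunit_b.id] = fam_b
        for d in range(spec.n_decoys_per_family):
            native = natives[-spec.members_per_family]  # family base member
            decoy = make_decoy(native, seed=int(rng.integers(0, 2**31 - 1)))
            did = f"F{f}d{d}"
            decoy = _relabel(decoy, did, fam_a, fam_b)
            decoys.append((native.id, decoy))
            labels[decoy.subunit_a.id] = fam_a
            labels[decoy.subunit_b.id] = fam_b

    rows = []
    for i, x in enumerate(natives):
        for y in natives[i + 1:]:
            rel = "homologous" if planted[x.id] == planted[y.id] else "unrelated"
            rows.append((x.id, y.id, rel))
    for native_id, decoy in decoys:
        rows.append((native_id, decoy.id, "native-decoy"))
    truth = pd.DataFrame(rows, columns=["id_1", "id_2", "relation"])
    return SyntheticCorpus(natives, decoys, labels, planted, truth)


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write each complex as a PDB file plus family-label and truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for inter in corpus.all_interactions:
        write_pdb([inter.subunit_a, inter.subunit_b], out / f"{inter.id}.pdb")
    with open(out / "families.tsv", "w") as fh:
        for sid in sorted(corpus.family_labels):
            fh.write(f"{sid}\t{corpus.family_labels[sid]}\n")
    corpus.truth_pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
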