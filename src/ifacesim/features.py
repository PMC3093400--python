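"""Per-interface 53-dimensional feature encoding.

The vector concatenates, in a fixed layout:

====== ==========================================================
index  feature
====== ==========================================================
1      number of residue contact pairs
2-29   occurrence frequencies of contacts between the 7
       physicochemical residue classes (28 unordered class pairs)
30     interface solvent-accessible surface area (Angstrom^2)
31     planarity: RMS deviation of interface atoms from the
       least-squares plane (Angstrom)
32     mean protrusion (CX) index of the contact residues
33     mean side-chain hydrophobicity (Fauchere-Pliska pi scale)
34-53  occurrence frequencies of each amino-acid type among the
       hot-spot residues (alphabetical three-letter order)
====== ==========================================================

Class pairs are enumerated row-major over the class order
[aliphatic, aromatic, positive, negative, small, hydrophobic, polar];
a contact whose residues belong to several classes increments every
matching pair, and the 28 bins are normalised by the total number of
increments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Interaction,
    Interface,
    Residue,
    ResidueId,
    STANDARD_RESIDUES,
    Subunit,
)

CLASS_NAMES: tuple[str, ...] = (
    "aliphatic", "aromatic", "positive", "negative", "small", "hydrophobic", "polar",
)

# class membership of the 20 standard residues (a residue may belong to
# several classes; PRO belongs only to "small")
_MEMBERSHIP: dict[str, tuple[int, ...]] = {
    #       ali aro pos neg sml hyd pol
    "ALA": (0, 0, 0, 0, 1, 1, 0),
    "ARG": (0, 0, 1, 0, 0, 0, 1),
    "ASN": (0, 0, 0, 0, 1, 0, 1),
    "ASP": (0, 0, 0, 1, 1, 0, 1),
    "CYS": (0, 0, 0, 0, 1, 1, 0),
    "GLU": (0, 0, 0, 1, 0, 0, 1),
    "GLN": (0, 0, 0, 0, 0, 0, 1),
    "GLY": (0, 0, 0, 0, 1, 1, 0),
    "HIS": (0, 1, 1, 0, 0, 1, 1),
    "ILE": (1, 0, 0, 0, 0, 1, 0),
    "LEU": (1, 0, 0, 0, 0, 1, 0),
    "LYS": (0, 0, 1, 0, 0, 1, 1),
    "MET": (0, 0, 0, 0, 0, 1, 0),
    "PHE": (0, 1, 0, 0, 0, 1, 0),
    "PRO": (0, 0, 0, 0, 1, 0, 0),
    "SER": (0, 0, 0, 0, 1, 0, 1),
    "THR": (0, 0, 0, 0, 1, 1, 1),
    "TRP": (0, 1, 0, 0, 0, 1, 1),
    "TYR": (0, 1, 0, 0, 0, 1, 1),
    "VAL": (1, 0, 0, 0, 1, 1, 0),
}

#: Fauchere-Pliska side-chain hydrophobicity (pi = log P relative to GLY)
FAUCHERE_PLISKA: dict[str, float] = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}

#: van der Waals radii by element for SASA, Angstrom
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}
_DEFAULT_RADIUS = 1.70

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})

#: positively / negatively charged residues (side-chain charge)
_POSITIVE_RES = frozenset({"ARG", "LYS", "HIS"})
_NEGATIVE_RES = frozenset({"ASP", "GLU"})


class ResidueClassTable:
    """7-class physicochemical membership of the 20 standard residues."""

    def __init__(self, membership: Mapping[str, tuple[int, ...]] = _MEMBERSHIP):
        self.classes = CLASS_NAMES
        self.matrix = np.array([membership[r] for r in STANDARD_RESIDUES], dtype=int)
        self._by_res = {r: np.flatnonzero(self.matrix[i]) for i, r in enumerate(STANDARD_RESIDUES)}

    def class_indices(self, res_type: str) -> np.ndarray:
        """Indices (into CLASS_NAMES) of the classes containing res_type."""
        return self._by_res.get(res_type, np.array([], dtype=int))

    def classes_of(self, res_type: str) -> list[str]:
        return [self.classes[i] for i in self.class_indices(res_type)]

    def members_of(self, cls: str) -> list[str]:
        j = self.classes.index(cls)
        return [r for i, r in enumerate(STANDARD_RESIDUES) if self.matrix[i, j]]


RESIDUE_CLASS_TABLE = ResidueClassTable()

#: row-major unordered class-pair order; PAIR_INDEX[(i, j)] with i <= j
PAIR_INDEX: dict[tuple[int, int], int] = {}
for _i in range(7):
    for _j in range(_i, 7):
        PAIR_INDEX[(_i, _j)] = len(PAIR_INDEX)
N_PAIR_BINS = len(PAIR_INDEX)  # 28


@dataclass
class FeatureVector53:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (53,):
            raise ValueError("feature vector must have 53 entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature value")
        for lo, hi in ((1, 29), (33, 53)):
            s = v[lo:hi].sum()
            if not (abs(s - 1.0) < 1e-9 or abs(s) < 1e-12):
                raise ValueError(f"frequency block [{lo}:{hi}] sums to {s}, not 0 or 1")
        self.values = v

    @property
    def n_contacts(self) -> float:
        return self.values[0]

    @property
    def group_pair_freq(self) -> np.ndarray:
        return self.values[1:29]

    @property
    def asa(self) -> float:
        return self.values[29]

    @property
    def planarity(self) -> float:
        return self.values[30]

    @property
    def protrusion(self) -> float:
        return self.values[31]

    @property
    def hydrophobicity(self) -> float:
        return self.values[32]

    @property
    def hotspot_freq(self) -> np.ndarray:
        return self.values[33:]


# ---------------------------------------------------------------------------
# Residue-class contact statistics

def group_pair_frequencies(
    iface: Interface,
    parents: Interaction,
    table: ResidueClassTable = RESIDUE_CLASS_TABLE,
) -> np.ndarray:
    """Normalised contact counts over the 28 unordered class pairs."""
    bins = np.zeros(N_PAIR_BINS)
    for rid_a, rid_b in iface.contacts:
        ca = table.class_indices(parents.subunit_a.residue(rid_a).res_type)
        cb = table.class_indices(parents.subunit_b.residue(rid_b).res_type)
        for i in ca:
            for j in cb:
                lo, hi = (i, j) if i <= j else (j, i)
                bins[PAIR_INDEX[(lo, hi)]] += 1.0
    total = bins.sum()
    if total > 0:
        bins /= total
    return bins


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)

def _golden_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _orientation_frame(coords: np.ndarray) -> np.ndarray:
    """Structure-intrinsic orthonormal frame (PCA axes, signs fixed by
    third-moment criterion) so that sphere sample points co-rotate with
    the structure and SASA is exactly rigid-motion invariant."""
    centered = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return np.eye(3)
    cov = centered.T @ centered
    w, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]
    for k in range(3):
        m3 = np.sum((centered @ vecs[:, k]) ** 3)
        if m3 < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Angstrom^2."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    frame = _orientation_frame(coords)
    sphere = _golden_sphere(n_points) @ frame.T
    ext = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    max_ext = ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= ext[j]
        out[i] = accessible.mean() * 4.0 * np.pi * ext[i] ** 2
    return out


def _atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)


def _heavy_atoms(res: Residue) -> list:
    return [a for a in res.atoms if a.element.upper() != "H"]


def residue_sasa(sub: Subunit, probe: float = 1.4, n_points: int = 960) -> dict[ResidueId, float]:
    """Per-residue SASA of the isolated subunit (sum over its atoms)."""
    coords, radii, owner = [], [], []
    for r in sub.residues:
        for a in r.atoms:
            coords.append(a.coord)
            radii.append(_atom_radius(a.element))
            owner.append(r.rid)
    areas = shrake_rupley_sasa(np.asarray(coords), np.asarray(radii), probe, n_points)
    out: dict[ResidueId, float] = {r.rid: 0.0 for r in sub.residues}
    for rid, area in zip(owner, areas):
        out[rid] += area
    return out


def interface_asa(iface: Interface, parents: Interaction) -> float:
    """Sum of the two binding-site ASAs, each the mean per-contact-residue
    SASA computed on the isolated (unbound) subunit."""
    total = 0.0
    for sub, site in (
        (parents.subunit_a, iface.site_a.residues),
        (parents.subunit_b, iface.site_b.residues),
    ):
        per_res = residue_sasa(sub)
        total += float(np.mean([per_res[rid] for rid in site]))
    return total


# ---------------------------------------------------------------------------
# Geometry features

def planarity(iface: Interface, parents: Interaction) -> float:
    """RMS deviation of all contact-residue atoms from the least-squares
    plane (the smallest-variance principal direction of the atom cloud)."""
    coords = _interface_atom_coords(iface, parents)
    if len(coords) < 3:
        raise ValueError("need at least 3 interface atoms")
    centered = coords - coords.mean(axis=0)
    w, _ = np.linalg.eigh(centered.T @ centered / len(coords))
    if w[1] < 1e-12:  # two vanishing variances: points are collinear
        raise ValueError("interface atoms are collinear")
    return float(np.sqrt(max(w[0], 0.0)))


def _interface_atom_coords(iface: Interface, parents: Interaction) -> np.ndarray:
    coords = []
    for sub, site in (
        (parents.subunit_a, iface.site_a.residues),
        (parents.subunit_b, iface.site_b.residues),
    ):
        for rid in sorted(site):
            coords.append(sub.residue(rid).coords)
    return np.concatenate(coords, axis=0)


SPHERE_RADIUS = 10.0  # CX neighbourhood radius, Angstrom
ATOM_VOLUME = 20.1  # mean non-hydrogen atomic volume, Angstrom^3


def protrusion(
    iface: Interface,
    parents: Interaction,
    sphere_radius: float = SPHERE_RADIUS,
    atom_volume: float = ATOM_VOLUME,
) -> float:
    """Mean CX protrusion index of the contact residues.

    For each heavy atom, the occupied volume within ``sphere_radius`` is
    estimated as (number of heavy atoms in the sphere, incl. itself) x
    ``atom_volume``; cx = (V_sphere - V_int) / V_int, clamped at 0.
    Residue index = mean over its atoms; feature = mean over all
    contact residues of both sites, each computed on the isolated
    subunit.
    """
    v_sphere = 4.0 / 3.0 * np.pi * sphere_radius**3
    residue_indices = []
    for sub, site in (
        (parents.subunit_a, iface.site_a.residues),
        (parents.subunit_b, iface.site_b.residues),
    ):
        heavy = np.array(
            [a.coord for r in sub.residues for a in _heavy_atoms(r)], dtype=float
        )
        tree = cKDTree(heavy)
        for rid in sorted(site):
            res = sub.residue(rid)
            cx = []
            for a in _heavy_atoms(res):
                n_in = len(tree.query_ball_point(a.xyz, sphere_radius))
                v_int = n_in * atom_volume
                cx.append(max((v_sphere - v_int) / v_int, 0.0))
            if cx:
                residue_indices.append(float(np.mean(cx)))
    return float(np.mean(residue_indices)) if residue_indices else 0.0


def hydrophobicity(
    iface: Interface,
    parents: Interaction,
    scale: Mapping[str, float] = FAUCHERE_PLISKA,
) -> float:
    """Mean hydrophobicity-scale value over all contact residues."""
    values = []
    for sub, site in (
        (parents.subunit_a, iface.site_a.residues),
        (parents.subunit_b, iface.site_b.residues),
    ):
        for rid in site:
            res_type = sub.residue(rid).res_type
            values.append(scale.get(res_type, 0.0))
    return float(np.mean(values)) if values else 0.0


# ---------------------------------------------------------------------------
# Hot spots

HOTSPOT_MIN_CONTACTS = 8  # weighted side-chain contact threshold
HOTSPOT_CONTACT_RADIUS = 5.0  # Angstrom
SALT_BRIDGE_RADIUS = 4.0  # Angstrom


def _is_charged_no(res: Residue, atom) -> int:
    """+1 / -1 for a charged side-chain N/O atom, else 0."""
    if atom.name in _BACKBONE or atom.name == "CB":
        return 0
    if res.res_type in _POSITIVE_RES and atom.element.upper() == "N":
        return 1
    if res.res_type in _NEGATIVE_RES and atom.element.upper() == "O":
        return -1
    return 0


def hotspot_scan(
    iface: Interface,
    parents: Interaction,
    min_contacts: int = HOTSPOT_MIN_CONTACTS,
    contact_radius: float = HOTSPOT_CONTACT_RADIUS,
    salt_bridge_radius: float = SALT_BRIDGE_RADIUS,
) -> set[ResidueId]:
    """Empirical alanine-scanning stand-in for hot-spot detection.

    A contact residue is a hot spot when its side-chain heavy atoms
    beyond Cbeta make at least ``min_contacts`` weighted inter-subunit
    heavy-atom contacts within ``contact_radius``; opposite-charge N/O
    pairs within ``salt_bridge_radius`` count double.  ALA and GLY have
    no side chain beyond Cbeta and are never hot spots.
    """
    hotspots: set[ResidueId] = set()
    for sub, partner, site in (
        (parents.subunit_a, parents.subunit_b, iface.site_a.residues),
        (parents.subunit_b, parents.subunit_a, iface.site_b.residues),
    ):
        partner_atoms = [
            (r, a) for r in partner.residues for a in _heavy_atoms(r)
        ]
        partner_coords = np.array([a.xyz for _, a in partner_atoms])
        tree = cKDTree(partner_coords)
        for rid in site:
            res = sub.residue(rid)
            if res.res_type in ("ALA", "GLY"):
                continue
            weighted = 0
            for a in _heavy_atoms(res):
                if a.name in _BACKBONE or a.name == "CB":
                    continue
                for j in tree.query_ball_point(a.xyz, contact_radius):
                    pres, patom = partner_atoms[j]
                    weighted += 1
                    qa, qb = _is_charged_no(res, a), _is_charged_no(pres, patom)
                    if (
                        qa * qb == -1
                        and np.linalg.norm(a.xyz - patom.xyz) <= salt_bridge_radius
                    ):
                        weighted += 1
            if weighted >= min_contacts:
                hotspots.add(rid)
    return hotspots


def hotspot_frequencies(
    hotspots: set[ResidueId], iface: Interface, parents: Interaction
) -> np.ndarray:
    """20-vector of hot-spot residue-type frequencies (alphabetical
    three-letter order); zero vector when there are no hot spots."""
    counts = np.zeros(20)
    order = {r: i for i, r in enumerate(STANDARD_RESIDUES)}
    for rid in hotspots:
        if rid in iface.site_a.residues:
            res_type = parents.subunit_a.residue(rid).res_type
        else:
            res_type = parents.subunit_b.residue(rid).res_type
        counts[order[res_type]] += 1.0
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


# ---------------------------------------------------------------------------
# Assembly

def feature_vector(iface: Interface, parents: Interaction) -> FeatureVector53:
    """Assemble the full 53-dimensional interface descriptor."""
    hotspots = hotspot_scan(iface, parents)
    values = np.concatenate(
        [
            [float(iface.n_contacts)],
            group_pair_frequencies(iface, parents),
            [
                interface_asa(iface, parents),
                planarity(iface, parents),
                protrusion(iface, parents),
                hydrophobicity(iface, parents),
            ],
            hotspot_frequencies(hotspots, iface, parents),
        ]
    )
    return FeatureVector53(values)
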