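"""Structure parsing and interface extraction.

A protein-protein *interaction* is a pair of subunits sharing one
coordinate frame; two residues are in contact when any atom of one lies
within a distance cutoff (default 6 Angstrom, inclusive) of any atom of
the other.  The residues of one subunit that touch the partner form a
*binding site*, and the interface is the triple (site_a, site_b,
contacts).

PDB files are read with gemmi.  Waters, ligands and other non-protein
groups are excluded; alternate locations are resolved to the
highest-occupancy conformer; modified residues are mapped to their
parent amino acid where the chemical-component tables declare one, and
dropped (with a log message) otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: the 20 standard three-letter amino-acid codes, alphabetical
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: residue identifier: (chain id, residue sequence number, insertion code)
ResidueId = tuple[str, int, str]


class StructureError(Exception):
    """Base class for structure-level failures."""


class MissingChainError(StructureError):
    """A requested chain (or residue range) is absent from the file."""


class EmptyChainError(StructureError):
    """A selected chain contains no standard amino-acid residues."""


class NoInterfaceError(StructureError):
    """Two subunits share no residue contacts at the given cutoff."""


class FamilyLabelError(StructureError):
    """Conflicting family labels for the same subunit id."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    icode: str
    res_type: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.rid} has no atoms")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"residue {self.rid} has non-finite coordinates")

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def ca(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.xyz
        return None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Subunit:
    """One interacting unit: a chain or a residue range of a chain."""

    id: str
    residues: list[Residue]
    family_label: str | None = None

    def __post_init__(self) -> None:
        rids = [r.rid for r in self.residues]
        if len(rids) != len(set(rids)):
            raise ValueError(f"duplicate residue ids in subunit {self.id}")
        self._index = {rid: r for rid, r in zip(rids, self.residues)}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, rid: ResidueId) -> Residue:
        return self._index[rid]

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [r.rid for r in self.residues]

    def ca_array(self) -> tuple[list[ResidueId], np.ndarray]:
        """Residue ids and Calpha coordinates for residues that have one."""
        rids, coords = [], []
        for r in self.residues:
            ca = r.ca
            if ca is not None:
                rids.append(r.rid)
                coords.append(ca)
        return rids, np.asarray(coords, dtype=float).reshape(-1, 3)

    def all_atoms(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues], axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Subunit":
        """A copy with every atom mapped through x -> R x + t."""
        new_res = []
        for r in self.residues:
            atoms = [
                Atom(a.name, a.element, tuple(rotation @ a.xyz + translation))
                for a in r.atoms
            ]
            new_res.append(Residue(r.chain_id, r.seq_id, r.icode, r.res_type, atoms))
        return Subunit(self.id, new_res, self.family_label)


@dataclass
class Interaction:
    subunit_a: Subunit
    subunit_b: Subunit
    id: str = ""

    def __post_init__(self) -> None:
        shared = set((r.chain_id, r.seq_id, r.icode) for r in self.subunit_a.residues) & set(
            (r.chain_id, r.seq_id, r.icode) for r in self.subunit_b.residues
        )
        if shared:
            raise ValueError(f"subunits share residue identifiers: {sorted(shared)[:3]} ...")
        if not self.id:
            self.id = f"{self.subunit_a.id}|{self.subunit_b.id}"

    @property
    def family_labels(self) -> tuple[str | None, str | None]:
        return (self.subunit_a.family_label, self.subunit_b.family_label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Interaction":
        return Interaction(
            self.subunit_a.transformed(rotation, translation),
            self.subunit_b.transformed(rotation, translation),
            id=self.id,
        )


@dataclass(frozen=True)
class BindingSite:
    parent_subunit_id: str
    residues: frozenset[ResidueId]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site is empty")


@dataclass
class Interface:
    site_a: BindingSite
    site_b: BindingSite
    contacts: frozenset[tuple[ResidueId, ResidueId]]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.contacts:
            raise ValueError("interface has no contacts")
        proj_a = {a for a, _ in self.contacts}
        proj_b = {b for _, b in self.contacts}
        if proj_a != set(self.site_a.residues) or proj_b != set(self.site_b.residues):
            raise ValueError("binding sites are not the projections of the contact set")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


# ---------------------------------------------------------------------------
# PDB reading

def _parent_res_type(name: str) -> str | None:
    """Map a residue name to a standard amino acid, or None."""
    if name in STANDARD_RESIDUES:
        return name
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        parent = _ONE_TO_THREE.get(info.one_letter_code.upper())
        if parent is not None:
            return parent
    return None


def _resolve_altloc(res: gemmi.Residue) -> list[Atom]:
    """Keep one atom per atom name: the highest-occupancy conformer."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    out = []
    for atom in best.values():
        el = atom.element.name if atom.element else ""
        out.append(Atom(atom.name, el, (atom.pos.x, atom.pos.y, atom.pos.z)))
    return out


def _parse_selection(sel: str) -> tuple[str, int | None, int | None]:
    """Parse 'A' or 'A:10-50' into (chain, start, end); range inclusive."""
    if ":" in sel:
        chain, rng = sel.split(":", 1)
        lo, hi = rng.split("-", 1)
        return chain, int(lo), int(hi)
    return sel, None, None


def read_complex(path: str | Path, chains: Sequence[str] | str) -> list[Subunit]:
    """Read selected chains (or chain:start-end ranges) as Subunits.

    Non-protein groups (waters, ligands) are skipped; modified residues
    are mapped to their parent standard residue where known.
    """
    if isinstance(chains, str):
        chains = [c.strip() for c in chains.split(",") if c.strip()]
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    chain_map = {ch.name: ch for ch in model}
    subunits = []
    for sel in chains:
        chain_name, lo, hi = _parse_selection(sel)
        if chain_name not in chain_map:
            raise MissingChainError(f"chain {chain_name!r} not found in {path}")
        residues = []
        seen = set()
        for res in chain_map[chain_name]:
            seq = res.seqid.num
            if lo is not None and not (lo <= seq <= hi):
                continue
            icode = res.seqid.icode.strip()
            key = (seq, icode)
            if key in seen:  # microheterogeneity: keep first occurrence
                continue
            parent = _parent_res_type(res.name)
            if parent is None:
                if res.name not in ("HOH", "WAT"):
                    logger.info("skipping non-standard residue %s %s%d", res.name, chain_name, seq)
                continue
            seen.add(key)
            residues.append(Residue(chain_name, seq, icode, parent, _resolve_altloc(res)))
        if not residues:
            raise EmptyChainError(f"selection {sel!r} has no standard residues in {path}")
        subunits.append(Subunit(sel, residues))
    return subunits


def write_pdb(subunits: Iterable[Subunit], path: str | Path) -> None:
    """Write subunits as a single-model PDB file (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = "ifacesim"
    model = gemmi.Model("1")
    for su in subunits:
        chain_ids = {r.chain_id for r in su.residues}
        for cid in sorted(chain_ids):
            chain = gemmi.Chain(cid)
            for r in su.residues:
                if r.chain_id != cid:
                    continue
                res = gemmi.Residue()
                res.name = r.res_type
                res.seqid = gemmi.SeqId(r.seq_id, r.icode or " ")
                for a in r.atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element or "C")
                    atom.pos = gemmi.Position(*(round(c, 3) for c in a.coord))
                    atom.occ = 1.0
                    atom.b_iso = 0.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Contacts and interfaces

def detect_contacts(
    sub_a: Subunit, sub_b: Subunit, cutoff: float = 6.0
) -> frozenset[tuple[ResidueId, ResidueId]]:
    """All residue pairs with any inter-atom distance <= cutoff (inclusive)."""
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("subunits must be non-empty")
    coords_a, owner_a = _flat_atoms(sub_a)
    coords_b, owner_b = _flat_atoms(sub_b)
    tree = cKDTree(coords_b)
    pairs = tree.query_ball_point(coords_a, r=cutoff)
    contacts = set()
    for ia, hits in enumerate(pairs):
        if not hits:
            continue
        ra = owner_a[ia]
        for ib in hits:
            contacts.add((ra, owner_b[ib]))
    return frozenset(contacts)


def _flat_atoms(sub: Subunit) -> tuple[np.ndarray, list[ResidueId]]:
    coords, owners = [], []
    for r in sub.residues:
        c = r.coords
        coords.append(c)
        owners.extend([r.rid] * len(c))
    return np.concatenate(coords, axis=0), owners


def build_interface(inter: Interaction, cutoff: float = 6.0) -> Interface:
    """Extract the interface (B1, B2, C) of an interaction."""
    contacts = detect_contacts(inter.subunit_a, inter.subunit_b, cutoff)
    if not contacts:
        raise NoInterfaceError(
            f"no residue contacts between {inter.subunit_a.id} and "
            f"{inter.subunit_b.id} at {cutoff} A"
        )
    site_a = BindingSite(inter.subunit_a.id, frozenset(a for a, _ in contacts))
    site_b = BindingSite(inter.subunit_b.id, frozenset(b for _, b in contacts))
    return Interface(site_a, site_b, contacts, id=inter.id)


# ---------------------------------------------------------------------------
# Family labels and serialization

def read_family_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV of (subunit id, family label).

    Unlisted subunits should be treated as label "unknown" by callers;
    duplicate ids with conflicting labels raise FamilyLabelError.
    """
    labels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FamilyLabelError(f"malformed family-label row: {line!r}")
        sid, lab = parts[0], parts[1]
        if sid in labels and labels[sid] != lab:
            raise FamilyLabelError(f"conflicting labels for {sid!r}: {labels[sid]!r} vs {lab!r}")
        labels[sid] = lab
    return labels


def family_label(labels: Mapping[str, str], subunit_id: str) -> str:
    return labels.get(subunit_id, "unknown")


def interface_to_json(iface: Interface) -> str:
    rec = {
        "id": iface.id,
        "site_a": {
            "parent": iface.site_a.parent_subunit_id,
            "residues": sorted(list(r) for r in iface.site_a.residues),
        },
        "site_b": {
            "parent": iface.site_b.parent_subunit_id,
            "residues": sorted(list(r) for r in iface.site_b.residues),
        },
        "contacts": sorted([list(a), list(b)] for a, b in iface.contacts),
    }
    return json.dumps(rec, indent=1)


def interface_from_json(text: str) -> Interface:
    rec = json.loads(text)

    def _rid(x) -> ResidueId:
        return (x[0], int(x[1]), x[2])

    contacts = frozenset((_rid(a), _rid(b)) for a, b in rec["contacts"])
    return Interface(
        BindingSite(rec["site_a"]["parent"], frozenset(_rid(r) for r in rec["site_a"]["residues"])),
        BindingSite(rec["site_b"]["parent"], frozenset(_rid(r) for r in rec["site_b"]["residues"])),
        contacts,
        id=rec.get("id", ""),
    )
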