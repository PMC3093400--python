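"""Shared fixtures: small synthetic structures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ifacesim.structure_io import Atom, Interaction, Residue, Subunit, build_interface
from ifacesim.synthetic import make_complex, make_family_template, make_homolog_pair

# small subunits keep the unit suite fast; the acceptance tests use the
# generator's full-size defaults
UNIT_SIZE = 30


@pytest.fixture(scope="session")
def template_a():
    return make_family_template(1, UNIT_SIZE, "A")


@pytest.fixture(scope="session")
def template_b():
    return make_family_template(2, UNIT_SIZE, "B")


@pytest.fixture(scope="session")
def complex_ab(template_a, template_b):
    return make_complex(template_a, template_b, seed=3)


@pytest.fixture(scope="session")
def interface_ab(complex_ab):
    return build_interface(complex_ab)


@pytest.fixture(scope="session")
def homolog_ab(complex_ab):
    return make_homolog_pair(complex_ab, noise_sd=1.0, mutation_rate=0.1, seed=4)


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent optimal-superposition RMSD via the Horn quaternion
    eigenvalue method (largest eigenvalue of the 4x4 key matrix)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    M = b0.T @ a0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(a0**2) + np.sum(b0**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_contacts(sub_a: Subunit, sub_b: Subunit, cutoff: float = 6.0):
    """All-pairs reference contact detection."""
    out = set()
    for ra in sub_a.residues:
        ca = ra.coords
        for rb in sub_b.residues:
            d = np.linalg.norm(ca[:, None, :] - rb.coords[None, :, :], axis=2)
            if d.min() <= cutoff:
                out.add((ra.rid, rb.rid))
    return frozenset(out)


def random_subunit(rng: np.random.Generator, chain: str, n_res: int = 5,
                   spread: float = 12.0) -> Subunit:
    """Random blob subunit for contact/property tests."""
    residues = []
    for i in range(n_res):
        center = rng.uniform(-spread, spread, size=3)
        atoms = [
            Atom(name, "C", tuple(center + rng.normal(0, 1.0, size=3)))
            for name in ("CA", "CB", "CG")
        ]
        residues.append(Residue(chain, i + 1, "", "ALA", atoms))
    return Subunit(chain, residues)


def simple_residue(chain: str, seq: int, res_type: str, atoms: list[tuple[str, str, tuple]]):
    return Residue(chain, seq, "", res_type, [Atom(n, e, c) for n, e, c in atoms])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
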