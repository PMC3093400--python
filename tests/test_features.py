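"""53-dimensional interface feature encoding and its components."""

from __future__ import annotations

import numpy as np
import pytest

from ifacesim.features import (
    ATOM_VOLUME,
    CLASS_NAMES,
    FAUCHERE_PLISKA,
    FeatureVector53,
    PAIR_INDEX,
    RESIDUE_CLASS_TABLE,
    SPHERE_RADIUS,
    feature_vector,
    group_pair_frequencies,
    hotspot_frequencies,
    hotspot_scan,
    hydrophobicity,
    interface_asa,
    planarity,
    protrusion,
    residue_sasa,
    shrake_rupley_sasa,
)
from ifacesim.structure_io import (
    Atom,
    BindingSite,
    Interaction,
    Interface,
    Residue,
    STANDARD_RESIDUES,
    Subunit,
    build_interface,
)

from conftest import random_rotation, simple_residue

# independent transcription of the published residue-class table
# (aliphatic, aromatic, positive, negative, small, hydrophobic, polar)
PUBLISHED_TABLE = {
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


def two_residue_interaction(res_a: Residue, res_b: Residue) -> tuple[Interaction, Interface]:
    inter = Interaction(Subunit("A", [res_a]), Subunit("B", [res_b]))
    iface = Interface(
        BindingSite("A", frozenset([res_a.rid])),
        BindingSite("B", frozenset([res_b.rid])),
        frozenset([(res_a.rid, res_b.rid)]),
    )
    return inter, iface


def single_atom_residue(chain: str, seq: int, res_type: str, xyz) -> Residue:
    return Residue(chain, seq, "", res_type, [Atom("CA", "C", tuple(xyz))])


class TestResidueClassTable:
    @pytest.mark.parametrize("res", STANDARD_RESIDUES)
    def test_membership_matches_published_table(self, res):
        row = RESIDUE_CLASS_TABLE.matrix[STANDARD_RESIDUES.index(res)]
        assert tuple(row) == PUBLISHED_TABLE[res]

    def test_seven_classes_and_every_residue_classified(self):
        assert len(CLASS_NAMES) == 7
        assert RESIDUE_CLASS_TABLE.matrix.shape == (20, 7)
        assert (RESIDUE_CLASS_TABLE.matrix.sum(axis=1) >= 1).all()
        assert RESIDUE_CLASS_TABLE.classes_of("PRO") == ["small"]

    def test_pair_bin_order_reproduces_published_feature_ids(self):
        # 1-based bin ids within the 28-bin block
        def bin_id(c1, c2):
            i, j = sorted((CLASS_NAMES.index(c1), CLASS_NAMES.index(c2)))
            return PAIR_INDEX[(i, j)] + 1

        assert bin_id("negative", "hydrophobic") == 21
        assert bin_id("polar", "polar") == 28
        assert bin_id("positive", "small") == 16
        assert bin_id("negative", "negative") == 19
        assert bin_id("aromatic", "hydrophobic") == 12
        assert bin_id("aliphatic", "aliphatic") == 1


class TestGroupPairFrequencies:
    def test_single_ala_ala_contact_brute_force(self):
        ra = single_atom_residue("A", 1, "ALA", (0, 0, 0))
        rb = single_atom_residue("B", 1, "ALA", (3, 0, 0))
        inter, iface = two_residue_interaction(ra, rb)
        freq = group_pair_frequencies(iface, inter)
        # brute-force: ALA in {small, hydrophobic}; pairs (s,s), (s,h) x2, (h,h)
        expected = np.zeros(28)
        classes = [CLASS_NAMES.index("small"), CLASS_NAMES.index("hydrophobic")]
        for i in classes:
            for j in classes:
                lo, hi = min(i, j), max(i, j)
                expected[PAIR_INDEX[(lo, hi)]] += 1
        expected /= expected.sum()
        assert np.allclose(freq, expected)
        assert freq.sum() == pytest.approx(1.0)

    def test_asp_arg_contact_fills_positive_negative_bin(self):
        ra = single_atom_residue("A", 1, "ASP", (0, 0, 0))
        rb = single_atom_residue("B", 1, "ARG", (3, 0, 0))
        inter, iface = two_residue_interaction(ra, rb)
        freq = group_pair_frequencies(iface, inter)
        i, j = sorted((CLASS_NAMES.index("positive"), CLASS_NAMES.index("negative")))
        assert freq[PAIR_INDEX[(i, j)]] > 0


class TestSasa:
    def test_single_free_atom_is_full_sphere(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert area[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_monte_carlo_oracle_on_random_cluster(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-2, 2, size=(6, 3))
        radii = np.full(6, 1.7)
        probe = 1.4
        areas = shrake_rupley_sasa(coords, radii, probe)
        # MC oracle: uniform points on each extended sphere
        n_mc = 200_000
        for i in range(6):
            pts = rng.normal(size=(n_mc, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[i] + (radii[i] + probe) * pts
            free = np.ones(n_mc, dtype=bool)
            for j in range(6):
                if j == i:
                    continue
                free &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j] + probe
            mc = free.mean() * 4 * np.pi * (radii[i] + probe) ** 2
            assert areas[i] == pytest.approx(mc, abs=max(0.02 * mc, 0.5))

    def test_caged_atom_is_buried(self):
        # surround one atom with a shell of neighbours
        shell = []
        for t in np.linspace(0, np.pi, 8):
            for p in np.linspace(0, 2 * np.pi, 16, endpoint=False):
                shell.append([3.0 * np.sin(t) * np.cos(p), 3.0 * np.sin(t) * np.sin(p), 3.0 * np.cos(t)])
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.7)
        areas = shrake_rupley_sasa(coords, radii)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_interface_asa_positive_on_generated_complex(self, complex_ab, interface_ab):
        asa = interface_asa(interface_ab, complex_ab)
        assert asa > 0

    def test_residue_sasa_rigid_invariance(self, template_a):
        rng = np.random.default_rng(2)
        moved = template_a.transformed(random_rotation(rng), rng.normal(size=3) * 15)
        s0 = residue_sasa(template_a)
        s1 = residue_sasa(moved)
        for rid in s0:
            assert s1[rid] == pytest.approx(s0[rid], abs=1e-6)


class TestPlanarity:
    def test_coplanar_atoms_zero(self):
        ra = Residue("A", 1, "", "GLY", [Atom("CA", "C", (x, y, 0.0)) for x in (0, 1, 2) for y in (0, 1)])
        rb = Residue("B", 1, "", "GLY", [Atom("CA", "C", (x, y, 0.0)) for x in (4, 5) for y in (0, 2)])
        inter, iface = two_residue_interaction(ra, rb)
        assert planarity(iface, inter) == pytest.approx(0.0, abs=1e-9)

    def test_two_planes_at_plus_minus_h(self):
        h = 1.7
        # in-plane spreads larger than h, so the smallest principal
        # direction is the plane normal
        pts_a = [(x, y, +h) for x in (0, 3, 6) for y in (0, 5)]
        pts_b = [(x, y, -h) for x in (0, 3, 6) for y in (0, 5)]
        ra = Residue("A", 1, "", "GLY", [Atom("CA", "C", p) for p in pts_a])
        rb = Residue("B", 1, "", "GLY", [Atom("CA", "C", p) for p in pts_b])
        inter, iface = two_residue_interaction(ra, rb)
        assert planarity(iface, inter) == pytest.approx(h, abs=1e-9)

    def test_collinear_atoms_error(self):
        ra = Residue("A", 1, "", "GLY", [Atom("CA", "C", (float(i), 0, 0)) for i in range(4)])
        rb = Residue("B", 1, "", "GLY", [Atom("CA", "C", (float(i) + 0.5, 0, 0)) for i in range(4)])
        inter, iface = two_residue_interaction(ra, rb)
        with pytest.raises(ValueError):
            planarity(iface, inter)


class TestProtrusion:
    def test_isolated_atom_reaches_analytic_maximum(self):
        ra = single_atom_residue("A", 1, "GLY", (0, 0, 0))
        rb = single_atom_residue("B", 1, "GLY", (5, 0, 0))
        inter, iface = two_residue_interaction(ra, rb)
        v_sphere = 4 / 3 * np.pi * SPHERE_RADIUS**3
        # each subunit holds one isolated atom: count 1, V_int = v
        expected = (v_sphere - ATOM_VOLUME) / ATOM_VOLUME
        assert protrusion(iface, inter) == pytest.approx(expected, rel=1e-9)

    def test_atom_in_dense_cluster_low_protrusion(self):
        rng = np.random.default_rng(0)
        # contact residue = single atom at the centre of a dense cloud
        # contributed by a neighbouring (non-contact) residue
        cloud = rng.uniform(-9, 9, size=(600, 3))
        ra = single_atom_residue("A", 1, "GLY", (0.0, 0.0, 0.0))
        ra_cloud = Residue("A", 2, "", "GLY", [
            Atom(f"X{i}", "C", tuple(c)) for i, c in enumerate(cloud)
        ])
        rb = single_atom_residue("B", 1, "GLY", (30.0, 0, 0))
        inter = Interaction(Subunit("A", [ra, ra_cloud]), Subunit("B", [rb]))
        iface = Interface(
            BindingSite("A", frozenset([ra.rid])),
            BindingSite("B", frozenset([rb.rid])),
            frozenset([(ra.rid, rb.rid)]),
        )
        v_iso = (4 / 3 * np.pi * SPHERE_RADIUS**3 - ATOM_VOLUME) / ATOM_VOLUME
        # subunit B still holds an isolated atom at the analytic maximum,
        # so the mean is dominated by it; compare per-site instead
        from ifacesim.features import protrusion as prot
        both = prot(iface, inter)
        assert both < 0.51 * v_iso  # buried site contributes ~0

    def test_helix_tip_more_protruding_than_middle(self, template_a):
        per_res = {}
        tree_atoms = np.array(
            [a.coord for r in template_a.residues for a in r.atoms if a.element != "H"]
        )
        from scipy.spatial import cKDTree

        tree = cKDTree(tree_atoms)
        for r in (template_a.residues[0], template_a.residues[7]):
            vals = []
            for a in r.atoms:
                n = len(tree.query_ball_point(np.array(a.coord), SPHERE_RADIUS))
                v_int = n * ATOM_VOLUME
                vals.append(max((4 / 3 * np.pi * SPHERE_RADIUS**3 - v_int) / v_int, 0))
            per_res[r.seq_id] = np.mean(vals)
        assert per_res[1] > per_res[8]  # helix end sticks out more


class TestHydrophobicity:
    def test_trp_only_interface(self):
        ra = single_atom_residue("A", 1, "TRP", (0, 0, 0))
        rb = single_atom_residue("B", 1, "TRP", (3, 0, 0))
        inter, iface = two_residue_interaction(ra, rb)
        assert hydrophobicity(iface, inter) == pytest.approx(FAUCHERE_PLISKA["TRP"])

    def test_two_types_average(self):
        ra = single_atom_residue("A", 1, "ILE", (0, 0, 0))
        rb = single_atom_residue("B", 1, "ASP", (3, 0, 0))
        inter, iface = two_residue_interaction(ra, rb)
        expected = (FAUCHERE_PLISKA["ILE"] + FAUCHERE_PLISKA["ASP"]) / 2
        assert hydrophobicity(iface, inter) == pytest.approx(expected)


def packed_arg_glu_fixture():
    """ARG side chain buried among three GLU side chains: enough
    weighted contacts (with doubled salt bridges) to be a hot spot."""
    arg = Residue("A", 1, "", "ARG", [
        Atom("N", "N", (-1.2, 0, 0)), Atom("CA", "C", (0, 0, 0)),
        Atom("C", "C", (1.2, 0, 0)), Atom("O", "O", (1.8, 1, 0)),
        Atom("CB", "C", (0, 1.5, 0)),
        Atom("CG", "C", (0, 2.9, 0)), Atom("NH1", "N", (0, 4.3, 0)),
    ])
    glus = []
    for k, (dx, dz) in enumerate(((-1.5, 0.5), (0.0, -0.8), (1.5, 0.5))):
        glus.append(Residue("B", k + 1, "", "GLU", [
            Atom("N", "N", (dx - 1.2, 8, dz)), Atom("CA", "C", (dx, 8, dz)),
            Atom("C", "C", (dx + 1.2, 8, dz)), Atom("O", "O", (dx + 1.8, 9, dz)),
            Atom("CB", "C", (dx, 6.6, dz)),
            Atom("CG", "C", (dx, 5.6, dz)), Atom("OE1", "O", (dx, 4.8, dz)),
        ]))
    inter = Interaction(Subunit("A", [arg]), Subunit("B", glus))
    return inter, build_interface(inter)


class TestHotspots:
    def test_gly_only_interface_has_no_hotspots(self):
        ra = single_atom_residue("A", 1, "GLY", (0, 0, 0))
        rb = single_atom_residue("B", 1, "GLY", (3, 0, 0))
        inter, iface = two_residue_interaction(ra, rb)
        assert hotspot_scan(iface, inter) == set()

    def test_packed_arg_against_glu_side_chains_is_hotspot(self):
        inter, iface = packed_arg_glu_fixture()
        hotspots = hotspot_scan(iface, inter)
        assert ("A", 1, "") in hotspots

    def test_side_chain_pointing_away_excluded(self):
        arg = Residue("A", 1, "", "ARG", [
            Atom("CA", "C", (0, 0, 0)), Atom("CB", "C", (0, -1.5, 0)),
            Atom("NH1", "N", (0, -4.0, 0)),  # points away from partner
        ])
        glu = Residue("B", 1, "", "GLU", [
            Atom("CA", "C", (0, 5.5, 0)), Atom("CB", "C", (0, 6, 0)),
            Atom("OE1", "O", (0, 7, 0)),
        ])
        inter, iface = two_residue_interaction(arg, glu)
        assert hotspot_scan(iface, inter) == set()

    def test_hotspot_frequencies(self):
        inter, iface = packed_arg_glu_fixture()
        hot = {("A", 1, ""), ("B", 1, ""), ("B", 2, "")}
        freq = hotspot_frequencies(hot, iface, inter)
        arg_i = STANDARD_RESIDUES.index("ARG")
        glu_i = STANDARD_RESIDUES.index("GLU")
        assert freq[arg_i] == pytest.approx(1 / 3)
        assert freq[glu_i] == pytest.approx(2 / 3)
        assert freq.sum() == pytest.approx(1.0)

    def test_no_hotspots_zero_vector(self, interface_ab, complex_ab):
        freq = hotspot_frequencies(set(), interface_ab, complex_ab)
        assert np.all(freq == 0)


class TestFeatureVector:
    def test_length_and_block_structure(self, complex_ab, interface_ab):
        fv = feature_vector(interface_ab, complex_ab)
        assert fv.values.shape == (53,)
        assert fv.n_contacts == interface_ab.n_contacts
        assert fv.group_pair_freq.sum() == pytest.approx(1.0)
        assert fv.hotspot_freq.sum() in (pytest.approx(0.0), pytest.approx(1.0))

    def test_deterministic(self, complex_ab, interface_ab):
        v1 = feature_vector(interface_ab, complex_ab).values
        v2 = feature_vector(interface_ab, complex_ab).values
        assert np.array_equal(v1, v2)

    def test_rigid_invariance(self, complex_ab, interface_ab):
        rng = np.random.default_rng(13)
        moved = complex_ab.transformed(random_rotation(rng), rng.normal(size=3) * 25)
        iface_m = build_interface(moved)
        v0 = feature_vector(interface_ab, complex_ab).values
        v1 = feature_vector(iface_m, moved).values
        assert np.allclose(v0, v1, atol=1e-6)

    def test_invalid_vector_rejected(self):
        bad = np.zeros(53)
        bad[1] = 0.5  # group-pair block sums to 0.5: neither 0 nor 1
        with pytest.raises(ValueError):
            FeatureVector53(bad)
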