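"""K-medoid clustering, silhouette K selection and A/C/H levels."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ifacesim.hierarchy import (
    DistanceMatrix,
    Hierarchy,
    build_levels,
    hierarchy_summary,
    kmedoid,
    select_k,
    silhouette,
)


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    D = cdist(points, points)
    np.fill_diagonal(D, 0.0)
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(ids, D)


def clustered_points(n_clusters: int, per_cluster: int, seed: int, spread=0.3, sep=10.0):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-sep, sep, size=(n_clusters, 2))
    pts, labels = [], []
    for c in range(n_clusters):
        pts.append(centers[c] + rng.normal(0, spread, size=(per_cluster, 2)))
        labels += [c] * per_cluster
    return np.vstack(pts), np.array(labels)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))  # diagonal
        with pytest.raises(ValueError):
            DistanceMatrix(["a"], np.zeros((2, 2)))  # shape


class TestKmedoid:
    def test_k_equals_n_zero_objective(self):
        pts, _ = clustered_points(2, 4, seed=0)
        dm = euclidean_dm(pts)
        labels, medoids = kmedoid(dm, k=len(dm), seed=0)
        assert sorted(medoids) == list(range(len(dm)))
        assert len(set(labels)) == len(dm)

    def test_two_separated_clusters_recovered(self):
        pts, truth = clustered_points(2, 8, seed=1)
        dm = euclidean_dm(pts)
        labels, _ = kmedoid(dm, k=2, seed=0)
        # same partition up to label names
        split = {tuple(sorted(np.flatnonzero(labels == v))) for v in set(labels)}
        expected = {tuple(range(8)), tuple(range(8, 16))}
        assert split == expected

    def test_matches_exhaustive_search_small_n(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, size=(8, 2))
        dm = euclidean_dm(pts)
        labels, medoids = kmedoid(dm, k=2, seed=0)
        got = dm.values[:, medoids].min(axis=1).sum()
        best = min(
            dm.values[:, list(pair)].min(axis=1).sum()
            for pair in itertools.combinations(range(8), 2)
        )
        assert got == pytest.approx(best)

    def test_k_out_of_range(self):
        dm = euclidean_dm(np.zeros((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(ValueError):
            kmedoid(dm, k=4)

    def test_deterministic_given_seed(self):
        pts, _ = clustered_points(3, 5, seed=4)
        dm = euclidean_dm(pts)
        l1, m1 = kmedoid(dm, 3, seed=9)
        l2, m2 = kmedoid(dm, 3, seed=9)
        assert np.array_equal(l1, l2) and np.array_equal(m1, m2)


class TestSilhouette:
    def test_tight_far_clusters_high(self):
        pts, truth = clustered_points(2, 10, seed=5, spread=0.1, sep=20.0)
        dm = euclidean_dm(pts)
        assert silhouette(dm, truth) > 0.9

    def test_random_uniform_near_zero(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 1, size=(30, 2))
            dm = euclidean_dm(pts)
            labels = rng.integers(0, 2, size=30)
            if len(set(labels)) < 2:
                continue
            vals.append(silhouette(dm, labels))
        assert abs(np.mean(vals)) < 0.15

    def test_identical_points_zero_by_convention(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        assert silhouette(dm, [0, 0, 1, 1]) == 0.0

    def test_single_cluster_rejected(self):
        pts, _ = clustered_points(2, 4, seed=6)
        dm = euclidean_dm(pts)
        with pytest.raises(ValueError):
            silhouette(dm, [0] * len(dm))


class TestSelectK:
    def test_planted_five_clusters_recovered(self):
        pts, truth = clustered_points(5, 6, seed=7, spread=0.3, sep=15.0)
        dm = euclidean_dm(pts)
        k = select_k(dm, range(2, 11), seed=0)
        assert k == 5
        labels, _ = kmedoid(dm, k, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_flat_curve_returns_smallest_k(self):
        # all points identical: silhouette 0 for every K
        dm = DistanceMatrix([f"p{i}" for i in range(8)], np.zeros((8, 8)))
        assert select_k(dm, [2, 3, 4], seed=0) == 2

    def test_argmax_option(self):
        pts, _ = clustered_points(3, 6, seed=8, spread=0.2, sep=12.0)
        dm = euclidean_dm(pts)
        assert select_k(dm, range(2, 8), seed=0, method="argmax") == 3

    def test_grid_too_small(self):
        dm = euclidean_dm(np.arange(6).reshape(3, 2).astype(float))
        with pytest.raises(ValueError):
            select_k(dm, [2, 3], seed=0)


class TestBuildLevels:
    def test_worked_example(self):
        partition = {x: 0 for x in ("xy", "xz", "wv")}
        pairs = {"xy": ("X", "Y"), "xz": ("X", "Z"), "wv": ("W", "V")}
        h = build_levels(partition, pairs)
        assert h.c_classes["xy"] == h.c_classes["xz"]
        assert h.c_classes["wv"] != h.c_classes["xy"]
        assert len({h.h_classes[x] for x in partition}) == 3

    def test_identical_pairs_single_c_and_h(self):
        partition = {x: 0 for x in "abc"}
        pairs = {x: ("X", "Y") for x in "abc"}
        h = build_levels(partition, pairs)
        assert len(set(h.c_classes.values())) == 1
        assert len(set(h.h_classes.values())) == 1

    def test_transitive_chain_merges_into_one_c_class(self):
        partition = {x: 0 for x in ("i1", "i2", "i3")}
        pairs = {"i1": ("X", "Y"), "i2": ("Y", "Z"), "i3": ("Z", "W")}
        h = build_levels(partition, pairs)
        assert len(set(h.c_classes.values())) == 1
        assert len(set(h.h_classes.values())) == 3

    def test_missing_label_singleton(self):
        partition = {"a": 0, "b": 0}
        pairs = {"a": ("X", "Y"), "b": ("unknown", "Y")}
        h = build_levels(partition, pairs)
        assert h.c_classes["a"] != h.c_classes["b"]

    def test_nesting_property_random_corpora(self):
        rng = np.random.default_rng(11)
        fams = [f"F{i}" for i in range(6)]
        for _ in range(10):
            ids = [f"i{j}" for j in range(15)]
            partition = {i: int(rng.integers(0, 3)) for i in ids}
            pairs = {i: (fams[rng.integers(0, 6)], fams[rng.integers(0, 6)]) for i in ids}
            h = build_levels(partition, pairs)
            # refinement: each H class within one C class within one A class
            for level_fine, level_coarse in ((h.h_classes, h.c_classes),
                                             (h.c_classes, h.a_classes)):
                mapping = {}
                for i in ids:
                    fine = level_fine[i]
                    assert mapping.setdefault(fine, level_coarse[i]) == level_coarse[i]

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        ids = [f"i{j}" for j in range(12)]
        partition = {i: int(rng.integers(0, 2)) for i in ids}
        pairs = {i: (f"F{rng.integers(0, 4)}", f"F{rng.integers(0, 4)}") for i in ids}
        h1 = build_levels(partition, pairs)
        shuffled = dict(reversed(list(partition.items())))
        h2 = build_levels(shuffled, pairs)

        def canon(classes):
            groups = {}
            for i, v in classes.items():
                groups.setdefault(v, set()).add(i)
            return {frozenset(g) for g in groups.values()}

        assert canon(h1.c_classes) == canon(h2.c_classes)
        assert canon(h1.h_classes) == canon(h2.h_classes)

    def test_summary_table(self):
        partition = {x: 0 for x in "abc"}
        pairs = {x: ("X", "Y") for x in "abc"}
        table = hierarchy_summary(build_levels(partition, pairs))
        assert list(table["level"]) == ["H", "C", "A"]
        assert (table["clusters"] == 1).all()
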