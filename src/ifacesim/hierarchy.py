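"""Hierarchical A/C/H classification of interfaces.

Interfaces are first clustered on the all-against-all SVM distance
matrix with K-medoids (PAM); the number of clusters is picked at the
knee of the mean-silhouette curve.  Each cluster is an A-level class
(members may be merely analogous).  Within an A class, interfaces
sharing at least one subunit family are connected; the connected
components are the C-level classes (common-partner analogous or
closer).  Within a C class, interfaces with identical unordered family
pairs form the H-level classes (homologous only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import silhouette_score


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        n = len(self.ids)
        if V.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if np.any(np.abs(np.diag(V)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if np.max(np.abs(V - V.T)) > 1e-9:
            raise ValueError("matrix must be symmetric within 1e-9")
        if np.any(V < 0):
            raise ValueError("distances must be nonnegative")
        self.values = V

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Hierarchy:
    """Nested partitions: every H class lies inside one C class inside
    one A class."""

    a_classes: dict[str, int]
    c_classes: dict[str, int]
    h_classes: dict[str, int]
    k: int


def _pam_objective(V: np.ndarray, medoids: np.ndarray) -> float:
    return float(V[:, medoids].min(axis=1).sum())


def _pam_once(V: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    n = len(V)
    medoids = rng.choice(n, size=k, replace=False)
    best_obj = _pam_objective(V, medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for candidate in range(n):
                if candidate in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = candidate
                obj = _pam_objective(V, trial)
                if obj < best_obj - 1e-12:
                    medoids, best_obj = trial, obj
                    improved = True
    return np.sort(medoids), best_obj


def kmedoid(
    d: DistanceMatrix,
    k: int,
    seed: int = 0,
    restarts: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """PAM K-medoids: seeded random medoid init, assignment to the
    nearest medoid, and greedy swaps until no swap lowers the sum of
    within-cluster distances; best of ``restarts`` seeded restarts.

    Returns (labels, medoid indices); labels are indices into the
    medoid array.
    """
    n = len(d)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    V = d.values
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    for _ in range(restarts):
        medoids, obj = _pam_once(V, k, rng)
        if best is None or obj < best[1]:
            best = (medoids, obj)
    medoids = best[0]
    labels = np.argmin(V[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # medoids belong to their own cluster
    return labels, medoids


def silhouette(d: DistanceMatrix, labels: Sequence[int]) -> float:
    """Mean silhouette width on a precomputed distance matrix;
    singleton clusters (and the all-identical-distances case)
    contribute 0 by convention."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(d.values, labels, metric="precomputed"))


def select_k(
    d: DistanceMatrix,
    k_grid: Sequence[int],
    seed: int = 0,
    method: str = "knee",
) -> int:
    """Number of clusters at the knee of the mean-silhouette curve.

    The knee is the grid point with maximum perpendicular distance to
    the chord joining the curve's endpoints (ties toward smaller K);
    ``method="argmax"`` picks the silhouette maximum instead.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if len(k_grid) < 3:
        raise ValueError("need a grid of at least 3 K values")
    scores = []
    for k in k_grid:
        labels, _ = kmedoid(d, k, seed=seed)
        if len(np.unique(labels)) < 2:
            scores.append(0.0)
        else:
            scores.append(silhouette(d, labels))
    scores = np.asarray(scores, float)
    if method == "argmax":
        return k_grid[int(np.argmax(scores))]
    x = np.asarray(k_grid, float)
    y = scores
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        return k_grid[0]
    # signed perpendicular distance of each point above the chord
    dists = ((x - p0[0]) * chord[1] - (y - p0[1]) * chord[0]) / norm
    dists = -dists  # positive = above the chord (silhouette bulge)
    best = int(np.argmax(dists))
    if dists[best] <= 1e-12:
        return k_grid[0]
    return k_grid[best]


def build_levels(
    partition: dict[str, int],
    family_pairs: dict[str, tuple[str, str]],
) -> Hierarchy:
    """Impose the C and H definitions on an A-level partition.

    ``family_pairs`` maps interface id to its (unordered) family-label
    pair.  Within each A class, C classes are the connected components
    of the share-a-family graph; within each C class, H classes group
    identical unordered label pairs.  Interfaces with a missing label
    form their own C/H class.
    """
    ids = sorted(partition)
    a_classes = {i: partition[i] for i in ids}
    c_classes: dict[str, int] = {}
    h_classes: dict[str, int] = {}
    next_c = 0
    next_h = 0
    for a_val in sorted(set(partition.values())):
        members = [i for i in ids if partition[i] == a_val]
        known = [i for i in members if _labels_of(family_pairs, i) is not None]
        unknown = [i for i in members if i not in known]
        # connected components of the share-a-family graph
        idx = {m: j for j, m in enumerate(known)}
        rows, cols = [], []
        for m1, m2 in itertools.combinations(known, 2):
            if set(_labels_of(family_pairs, m1)) & set(_labels_of(family_pairs, m2)):
                rows.append(idx[m1])
                cols.append(idx[m2])
        n_k = len(known)
        if n_k:
            graph = csr_matrix(
                (np.ones(2 * len(rows)), (rows + cols, cols + rows)), shape=(n_k, n_k)
            )
            n_comp, comp = connected_components(graph, directed=False)
        else:
            n_comp, comp = 0, np.array([], dtype=int)
        for c_local in range(n_comp):
            c_members = [known[j] for j in range(n_k) if comp[j] == c_local]
            for m in c_members:
                c_classes[m] = next_c
            # H: identical unordered family pairs inside the C class
            by_pair: dict[tuple[str, str], list[str]] = {}
            for m in c_members:
                by_pair.setdefault(_sorted_pair(family_pairs[m]), []).append(m)
            for pair_members in by_pair.values():
                for m in pair_members:
                    h_classes[m] = next_h
                next_h += 1
            next_c += 1
        for m in unknown:  # missing label: singleton C and H class
            c_classes[m] = next_c
            h_classes[m] = next_h
            next_c += 1
            next_h += 1
    return Hierarchy(a_classes, c_classes, h_classes, k=len(set(partition.values())))


def _labels_of(family_pairs, i):
    pair = family_pairs.get(i)
    if pair is None:
        return None
    if "unknown" in pair or None in pair:
        return None
    return pair


def _sorted_pair(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def hierarchy_summary(h: Hierarchy) -> "pd.DataFrame":
    """Per-level cluster-count summary (clusters, avg/min/max size,
    number of 1-member clusters)."""
    import pandas as pd

    rows = []
    for level, classes in (("H", h.h_classes), ("C", h.c_classes), ("A", h.a_classes)):
        sizes = np.array(list(_class_sizes(classes).values()))
        rows.append((
            level, len(sizes), float(sizes.mean()), int(sizes.min()),
            int(sizes.max()), int((sizes == 1).sum()),
        ))
    return pd.DataFrame(rows, columns=["level", "clusters", "avg", "min", "max", "one_member"])


def _class_sizes(classes: dict[str, int]) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for v in classes.values():
        sizes[v] = sizes.get(v, 0) + 1
    return sizes
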