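"""M-Tree indexing and similar-interface retrieval.

The M-Tree organises objects by a distance function alone: leaves hold
object ids, internal nodes hold routing objects with covering radii
bounding every object in their subtree.  k-NN search descends only
branches whose lower bound d(q, routing) - radius can still beat the
current k-th best distance.

The SVM interface distance is only empirically metric, so search
correctness cannot lean on the triangle inequality: an optional slack
``eps`` (set to the observed maximum violation of a corpus) loosens
pruning, and the tests verify exact agreement with a linear scan.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np

NODE_CAPACITY = 8

Distance = Callable[[Hashable, Hashable], float]


@dataclass
class _Entry:
    obj: Hashable
    radius: float = 0.0  # 0 for leaf entries
    child: "_Node | None" = None


@dataclass
class _Node:
    is_leaf: bool
    entries: list[_Entry] = field(default_factory=list)


class EmptyIndexError(Exception):
    pass


class MTreeIndex:
    """Metric tree over object ids with a user-supplied distance.

    Node capacity 8; splits promote the pair of objects minimising the
    larger covering radius (mM_RAD) and partition the remaining entries
    to the closer promoted object (generalised hyperplane).
    """

    def __init__(self, distance: Distance, capacity: int = NODE_CAPACITY, eps: float = 0.0):
        if capacity < 2:
            raise ValueError("capacity must be >= 2")
        self._d = distance
        self.capacity = capacity
        self.eps = eps
        self.root: _Node = _Node(is_leaf=True)
        self.size = 0

    # -- construction -------------------------------------------------

    @classmethod
    def build(
        cls,
        objects: Sequence[Hashable],
        distance: Distance,
        capacity: int = NODE_CAPACITY,
        eps: float = 0.0,
    ) -> "MTreeIndex":
        """Insert objects one by one in the given (deterministic) order."""
        index = cls(distance, capacity, eps)
        for obj in objects:
            index.insert(obj)
        return index

    def insert(self, obj: Hashable) -> None:
        split = self._insert(self.root, obj)
        if split is not None:
            e1, e2 = split
            self.root = _Node(is_leaf=False, entries=[e1, e2])
        self.size += 1

    def _insert(self, node: _Node, obj: Hashable) -> tuple[_Entry, _Entry] | None:
        if node.is_leaf:
            node.entries.append(_Entry(obj))
        else:
            best = None  # (not_covered, cost, idx)
            for i, e in enumerate(node.entries):
                dist = self._d(obj, e.obj)
                covered = dist <= e.radius
                cost = dist if covered else dist - e.radius
                key = (not covered, cost, i)
                if best is None or key < best[0]:
                    best = (key, i, dist)
            _, idx, dist = best
            entry = node.entries[idx]
            entry.radius = max(entry.radius, dist)
            child_split = self._insert(entry.child, obj)
            if child_split is not None:
                node.entries.pop(idx)
                node.entries.extend(child_split)
        if len(node.entries) > self.capacity:
            return self._split(node)
        return None

    def _split(self, node: _Node) -> tuple[_Entry, _Entry]:
        entries = node.entries
        n = len(entries)
        dmat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            dmat[i, j] = dmat[j, i] = self._d(entries[i].obj, entries[j].obj)

        def covering_radius(p: int, group: list[int]) -> float:
            if not group:
                return 0.0
            return max(dmat[p, g] + entries[g].radius for g in group)

        best = None  # (max_radius, i, j, group_i, group_j)
        for i, j in itertools.combinations(range(n), 2):
            gi, gj = [], []
            for k in range(n):
                (gi if dmat[i, k] <= dmat[j, k] else gj).append(k)
            ri, rj = covering_radius(i, gi), covering_radius(j, gj)
            key = (max(ri, rj), i, j)
            if best is None or key < best[0]:
                best = (key, i, j, gi, gj, ri, rj)
        _, i, j, gi, gj, ri, rj = best
        node_i = _Node(node.is_leaf, [entries[k] for k in gi])
        node_j = _Node(node.is_leaf, [entries[k] for k in gj])
        return (
            _Entry(entries[i].obj, ri, node_i),
            _Entry(entries[j].obj, rj, node_j),
        )

    # -- search -------------------------------------------------------

    def nearest(self, query: Hashable, k: int = 1) -> list[tuple[Hashable, float]]:
        """The k objects nearest to ``query``, ties broken by id.

        Branch-and-bound over the tree; a subtree is pruned only when
        its lower bound (minus the violation slack ``eps``) strictly
        exceeds the current k-th best distance, so equal-distance
        candidates are always examined.
        """
        if self.size == 0:
            raise EmptyIndexError("index is empty")
        k = min(k, self.size)
        candidates: list[tuple[float, Hashable]] = []
        worst = np.inf

        heap: list[tuple[float, int, _Node]] = [(0.0, 0, self.root)]
        counter = 1
        while heap:
            bound, _, node = heapq.heappop(heap)
            if bound > worst:
                continue
            for e in node.entries:
                dist = self._d(query, e.obj)
                if node.is_leaf:
                    candidates.append((dist, e.obj))
                    candidates.sort(key=lambda t: (t[0], str(t[1])))
                    if len(candidates) >= k:
                        worst = candidates[k - 1][0]
                else:
                    lower = max(dist - e.radius - self.eps, 0.0)
                    if lower <= worst:
                        heapq.heappush(heap, (lower, counter, e.child))
                        counter += 1
        return [(obj, dist) for dist, obj in candidates[:k]]

    # -- invariants (used by tests and sanity checks) ------------------

    def check_invariants(self) -> None:
        """Covering radii bound their subtrees; leaves at equal depth."""
        depths: set[int] = set()

        def walk(node: _Node, depth: int) -> list[Hashable]:
            if node.is_leaf:
                depths.add(depth)
                return [e.obj for e in node.entries]
            objs: list[Hashable] = []
            for e in node.entries:
                sub = walk(e.child, depth + 1)
                for o in sub:
                    if self._d(e.obj, o) > e.radius + 1e-9:
                        raise AssertionError(
                            f"covering radius violated at {e.obj!r}: "
                            f"{self._d(e.obj, o)} > {e.radius}"
                        )
                objs.extend(sub)
            return objs

        walk(self.root, 0)
        if len(depths) > 1:
            raise AssertionError(f"leaves at unequal depths: {sorted(depths)}")

    def __len__(self) -> int:
        return self.size


def linear_scan(
    objects: Sequence[Hashable], query: Hashable, distance: Distance, k: int = 1
) -> list[tuple[Hashable, float]]:
    """Reference exhaustive k-NN (ties by id), for verification."""
    scored = sorted(((distance(query, o), o) for o in objects),
                    key=lambda t: (t[0], str(t[1])))
    return [(o, d) for d, o in scored[:k]]


def retrieval_error(
    query: Hashable,
    retrieved: Hashable,
    corpus: Sequence[Hashable],
    iirmsd_of: Callable[[Hashable, Hashable], float | None],
) -> float:
    """Excess iiRMSD of the retrieved interface over the best
    achievable in the corpus (query excluded); >= 0 by construction.
    Corpus members with undefined iiRMSD are skipped."""
    v_retrieved = iirmsd_of(query, retrieved)
    if v_retrieved is None:
        raise ValueError("iiRMSD between query and retrieved is undefined")
    values = []
    for other in corpus:
        if other == query:
            continue
        v = iirmsd_of(query, other)
        if v is not None:
            values.append(v)
    if not values:
        raise ValueError("iiRMSD undefined against the whole corpus")
    return v_retrieved - min(values)
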