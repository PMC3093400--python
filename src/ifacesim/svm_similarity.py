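"""Feature-based interface similarity learned with a support vector machine.

Two interfaces are encoded as a 106-dimensional pair vector (the two
53-vectors minus their contact counts, i.e. indices 2-53 of each,
followed by the absolute differences of contact count and of interface
ASA).  A soft-margin SVM trained on similar/dissimilar interface pairs
yields the similarity

    delta(I1, I2) = signed distance of the pair vector from the
                    separating surface,

converted to a dissimilarity by subtracting from the maximum delta
observed on the training corpus (floored at zero).  Pair order is
canonicalised (larger contact count first, ties by ASA then id) so
delta and the distance are symmetric functions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVC

from .features import FeatureVector53

N_PAIR_FEATURES = 106


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel configuration.

    Defaults: RBF with soft margin C = 1 and variance-adaptive gamma
    (``None`` means 1 / (n_features * Var[X]) computed on the scaled
    training data, the standard "scale" heuristic; a plain 1/106 is far
    too smooth once features are min-max scaled).  The polynomial
    alternative uses degree 3, coef0 = 1.
    """

    kind: Literal["rbf", "poly"] = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0
    C: float = 1.0

    def resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma is not None:
            return self.gamma
        var = float(X.var())
        if var <= 0:
            return 1.0 / X.shape[1]
        return 1.0 / (X.shape[1] * var)


def pair_vector(
    v1: FeatureVector53,
    v2: FeatureVector53,
    id1: str = "",
    id2: str = "",
) -> np.ndarray:
    """106-dim pair encoding with canonical interface order.

    The interface with the larger contact count comes first (ties:
    larger ASA, then lexicographically smaller id), making the encoding
    symmetric in its arguments.
    """
    key1 = (-v1.n_contacts, -v1.asa, id1)
    key2 = (-v2.n_contacts, -v2.asa, id2)
    if key2 < key1:
        v1, v2 = v2, v1
    return np.concatenate([
        v1.values[1:],
        v2.values[1:],
        [abs(v1.n_contacts - v2.n_contacts)],
        [abs(v1.asa - v2.asa)],
    ])


@dataclass
class EvalReport:
    """Binary-classification counts with the standard derived rates."""

    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    @property
    def n(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn

    @property
    def f_ac(self) -> float:
        return (self.n_tp + self.n_tn) / self.n if self.n else float("nan")

    @property
    def f_pr(self) -> float:
        d = self.n_tp + self.n_fp
        return self.n_tp / d if d else float("nan")

    @property
    def f_re(self) -> float:
        d = self.n_tp + self.n_fn
        return self.n_tp / d if d else float("nan")


class SimilarityModel:
    """Trained kernel classifier defining delta and its distance.

    The decision function is evaluated from the stored support vectors
    directly, so a serialised model reproduces decision values
    bit-for-bit.
    """

    def __init__(
        self,
        spec: KernelSpec,
        support_vectors: np.ndarray,
        dual_coef: np.ndarray,
        intercept: float,
        scale_min: np.ndarray,
        scale_range: np.ndarray,
        delta_max: float,
    ):
        if spec.gamma is None:
            raise ValueError("a trained model must carry a concrete gamma")
        self.spec = spec
        self.support_vectors = np.asarray(support_vectors, float)
        self.dual_coef = np.asarray(dual_coef, float).ravel()
        self.intercept = float(intercept)
        self.scale_min = np.asarray(scale_min, float)
        self.scale_range = np.asarray(scale_range, float)
        if not np.isfinite(delta_max):
            raise ValueError("delta_max must be finite")
        self.delta_max = float(delta_max)

    # -- scoring ------------------------------------------------------

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_min) / self.scale_range

    def _kernel(self, X: np.ndarray) -> np.ndarray:
        S = self.support_vectors
        if self.spec.kind == "rbf":
            d2 = ((X[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-self.spec.gamma * d2)
        prod = self.spec.gamma * (X @ S.T) + self.spec.coef0
        return prod ** self.spec.degree

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self._kernel(self._scale(X)) @ self.dual_coef + self.intercept

    def delta(self, v1: FeatureVector53, v2: FeatureVector53,
              id1: str = "", id2: str = "") -> float:
        """Similarity: signed distance from the separating surface."""
        return float(self.decision_values(pair_vector(v1, v2, id1, id2))[0])

    def to_distance(self, delta_value: float) -> float:
        """delta_max - delta, floored at 0 above the training maximum."""
        return max(self.delta_max - delta_value, 0.0)

    def distance(self, v1: FeatureVector53, v2: FeatureVector53,
                 id1: str = "", id2: str = "") -> float:
        return self.to_distance(self.delta(v1, v2, id1, id2))

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        rec = {
            "kernel": {
                "kind": self.spec.kind, "gamma": self.spec.gamma,
                "degree": self.spec.degree, "coef0": self.spec.coef0,
                "C": self.spec.C,
            },
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "scale_min": self.scale_min.tolist(),
            "scale_range": self.scale_range.tolist(),
            "delta_max": self.delta_max,
        }
        Path(path).write_text(json.dumps(rec))

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityModel":
        rec = json.loads(Path(path).read_text())
        k = rec["kernel"]
        return cls(
            KernelSpec(k["kind"], k["gamma"], k["degree"], k["coef0"], k["C"]),
            np.array(rec["support_vectors"]),
            np.array(rec["dual_coef"]),
            rec["intercept"],
            np.array(rec["scale_min"]),
            np.array(rec["scale_range"]),
            rec["delta_max"],
        )


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0  # constant features map to 0
    return lo, rng


def _fit_svc(X: np.ndarray, y: np.ndarray, spec: KernelSpec) -> tuple[SVC, float]:
    gamma = spec.resolve_gamma(X)
    svc = SVC(
        kernel=spec.kind, C=spec.C, gamma=gamma,
        degree=spec.degree, coef0=spec.coef0,
    )
    svc.fit(X, y)
    return svc, gamma


def train(
    positives: Sequence[np.ndarray],
    negatives: Sequence[np.ndarray],
    spec: KernelSpec = KernelSpec(),
    seed: int = 0,
) -> SimilarityModel:
    """Fit the similarity SVM on pair vectors (positives = similar).

    Features are min-max scaled to [0, 1] on the training data;
    delta_max is the maximum decision value over the training pairs.
    Training is deterministic; ``seed`` fixes the (order-preserving)
    sample arrangement for reproducibility of serialised models.
    """
    if len(positives) < 10 or len(negatives) < 10:
        raise ValueError("need at least 10 pairs per class")
    X = np.vstack([np.asarray(positives, float), np.asarray(negatives, float)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    if X.shape[1] != N_PAIR_FEATURES:
        raise ValueError(f"pair vectors must have {N_PAIR_FEATURES} features")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    X, y = X[order], y[order]
    lo, rng_ = _fit_scaler(X)
    Xs = (X - lo) / rng_
    svc, gamma = _fit_svc(Xs, y, spec)
    decision = svc.decision_function(Xs)
    model = SimilarityModel(
        KernelSpec(spec.kind, gamma, spec.degree, spec.coef0, spec.C),
        svc.support_vectors_,
        svc.dual_coef_,
        float(svc.intercept_[0]),
        lo,
        rng_,
        float(decision.max()),
    )
    return model


def loocv(
    positives: Sequence[np.ndarray],
    negatives: Sequence[np.ndarray],
    spec: KernelSpec = KernelSpec(),
) -> EvalReport:
    """Leave-one-out cross-validation; scaling is re-fit on each
    training fold (no leakage)."""
    X = np.vstack([np.asarray(positives, float), np.asarray(negatives, float)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    if len(y) < 20:
        raise ValueError("need at least 20 pairs for LOOCV")
    tp = tn = fp = fn = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        lo, rng_ = _fit_scaler(X[mask])
        svc, _ = _fit_svc((X[mask] - lo) / rng_, y[mask], spec)
        pred = svc.predict(((X[i] - lo) / rng_).reshape(1, -1))[0]
        if y[i] == 1 and pred == 1:
            tp += 1
        elif y[i] == 0 and pred == 0:
            tn += 1
        elif y[i] == 0 and pred == 1:
            fp += 1
        else:
            fn += 1
    return EvalReport(tp, tn, fp, fn)


def rank_features(
    positives: Sequence[np.ndarray],
    negatives: Sequence[np.ndarray],
    C: float = 1.0,
) -> list[int]:
    """SVM recursive feature elimination with a linear kernel.

    Iteratively retrains on the surviving features and removes the one
    with the smallest weight magnitude (ties: the larger feature id is
    eliminated first).  Returns 1-based feature ids, most important
    first (reverse elimination order).
    """
    X = np.vstack([np.asarray(positives, float), np.asarray(negatives, float)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    lo, rng_ = _fit_scaler(X)
    Xs = (X - lo) / rng_
    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        svc = SVC(kernel="linear", C=C)
        svc.fit(Xs[:, surviving], y)
        w = np.abs(np.asarray(svc.coef_).ravel())
        # smallest |w|; ties resolved toward the larger feature id
        min_w = w.min()
        tied = [surviving[k] for k in range(len(surviving)) if w[k] <= min_w + 1e-15]
        drop = max(tied)
        surviving.remove(drop)
        eliminated.append(drop)
    eliminated.extend(surviving)
    return [f + 1 for f in reversed(eliminated)]


def select_kernel(
    positives: Sequence[np.ndarray],
    negatives: Sequence[np.ndarray],
    kind: Literal["rbf", "poly"] = "rbf",
    gamma_factors: Sequence[float] = (0.5, 1.0, 2.0, 4.0, 8.0),
    C_grid: Sequence[float] = (1.0, 10.0),
) -> KernelSpec:
    """Choose gamma and C by leave-one-out accuracy on the training
    pairs (standard SVM model selection).

    Gamma candidates are multiples of the variance-adaptive "scale"
    heuristic; ties prefer the smoother kernel and the smaller C.
    """
    X = np.vstack([np.asarray(positives, float), np.asarray(negatives, float)])
    lo, rng_ = _fit_scaler(X)
    base = KernelSpec(kind=kind).resolve_gamma((X - lo) / rng_)
    best: tuple[tuple[float, int, int], KernelSpec] | None = None
    for ci, C in enumerate(C_grid):
        for gi, f in enumerate(gamma_factors):
            spec = KernelSpec(kind=kind, gamma=base * f, C=C)
            acc = loocv(positives, negatives, spec).f_ac
            key = (-acc, gi, ci)
            if best is None or key < best[0]:
                best = (key, spec)
    return best[1]


# ---------------------------------------------------------------------------
# Corpus-level utilities

def distance_matrix(
    model: SimilarityModel,
    vectors: Sequence[FeatureVector53],
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Symmetric all-against-all SVM distance matrix, zero diagonal."""
    n = len(vectors)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = model.distance(vectors[i], vectors[j], ids[i], ids[j])
        D[i, j] = D[j, i] = d
    return D


def triangle_violation_rate(D: np.ndarray, tol: float = 1e-9) -> float:
    """Fraction of ordered triples (i, j, k) with
    D[i, k] > D[i, j] + D[j, k] + tol."""
    D = np.asarray(D, float)
    n = len(D)
    if n < 3:
        return 0.0
    # broadcast: via[i, j, k] = D[i, j] + D[j, k]
    via = D[:, :, None] + D[None, :, :]
    direct = D[:, None, :]
    viol = direct > via + tol
    idx = np.arange(n)
    viol[idx, idx, :] = False
    viol[:, idx, idx] = False
    viol[idx, :, idx] = False
    total = n * (n - 1) * (n - 2)
    return float(viol.sum()) / total
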