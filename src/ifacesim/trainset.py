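"""Training-set construction from structure-based similarity.

Positive pairs are *similar* interfaces: within-family (homologous)
pairs and cross-family pairs sharing one subunit family
(common-partner analogous), both kept when iiRMSD < 8 Angstrom.
Negative pairs are *dissimilar*: native-decoy pairs and native-native
pairs with four distinct family labels, kept when 15 < iiRMSD < 25
Angstrom (the upper bound excludes gross alignment failures).
Distributions of similarity values are compared with the
Bhattacharyya-coefficient distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .structure_io import Interaction
from .superpose import CachedAligner, iirmsd

POSITIVE_THRESHOLD = 8.0  # Angstrom, strict upper bound
NEGATIVE_LOW = 15.0  # Angstrom, strict lower bound
NEGATIVE_HIGH = 25.0  # Angstrom, strict upper bound

Relation = Literal["homologous", "common-partner", "unrelated", "native-decoy"]


@dataclass
class LabeledPair:
    id_1: str
    id_2: str
    iirmsd: float | None
    relation: Relation
    label: Literal["positive", "negative", "excluded"]


def _label_pair(inter: Interaction) -> tuple[str, str]:
    la, lb = inter.family_labels
    la = la or "unknown"
    lb = lb or "unknown"
    return (la, lb) if la <= lb else (lb, la)


def group_by_family(
    corpus: Sequence[Interaction],
) -> dict[tuple[str, str], list[Interaction]]:
    """Partition interactions by their unordered family-label pair.

    Groups of fewer than two members are kept in the output (callers
    needing candidate pairs skip them); ``eligible_groups`` filters.
    """
    groups: dict[tuple[str, str], list[Interaction]] = {}
    for inter in corpus:
        groups.setdefault(_label_pair(inter), []).append(inter)
    return groups


def eligible_groups(
    groups: dict[tuple[str, str], list[Interaction]]
) -> dict[tuple[str, str], list[Interaction]]:
    return {k: v for k, v in groups.items() if len(v) >= 2}


def default_measure(min_coverage: float = 0.6) -> Callable:
    """iiRMSD with a shared alignment cache, suitable for corpus loops."""
    aligner = CachedAligner()

    def measure(x: Interaction, y: Interaction, scenarios=None) -> float | None:
        return iirmsd(x, y, scenarios=scenarios, aligner=aligner,
                      min_coverage=min_coverage).value

    return measure


def _shared_family_scenarios(x: Interaction, y: Interaction) -> list[tuple[int, int]] | None:
    """Scenario pairings aligning the subunits that share exactly one
    family label, or None when the share is not exactly one."""
    lx = [s.family_label or "unknown" for s in (x.subunit_a, x.subunit_b)]
    ly = [s.family_label or "unknown" for s in (y.subunit_a, y.subunit_b)]
    shared = set(lx) & set(ly)
    if len(shared) != 1:
        return None
    f = shared.pop()
    if lx.count(f) > 1 or ly.count(f) > 1:
        return None  # homodimer-style share: not "exactly one subunit"
    return [(lx.index(f), ly.index(f))]


def build_positive(
    groups: dict[tuple[str, str], list[Interaction]],
    measure: Callable | None = None,
    threshold: float = POSITIVE_THRESHOLD,
) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Positive_H (within-group) and Positive_C (one shared family) pairs.

    A candidate is positive when iiRMSD < ``threshold`` (strict); for
    Positive_C the iiRMSD is restricted to the scenario aligning the
    shared-family subunits, the only structurally meaningful pairing.
    """
    if measure is None:
        measure = default_measure()
    pos_h: list[LabeledPair] = []
    for key, members in eligible_groups(groups).items():
        for x, y in itertools.combinations(members, 2):
            v = measure(x, y)
            label = "positive" if (v is not None and v < threshold) else "excluded"
            pos_h.append(LabeledPair(x.id, y.id, v, "homologous", label))
    pos_c: list[LabeledPair] = []
    keys = list(groups)
    for ka, kb in itertools.combinations(keys, 2):
        for x in groups[ka]:
            for y in groups[kb]:
                scenarios = _shared_family_scenarios(x, y)
                if scenarios is None:
                    continue
                v = measure(x, y, scenarios=scenarios)
                label = "positive" if (v is not None and v < threshold) else "excluded"
                pos_c.append(LabeledPair(x.id, y.id, v, "common-partner", label))
    return pos_h, pos_c


def build_negative(
    native_pairs: Sequence[tuple[Interaction, Interaction]],
    decoy_pairs: Sequence[tuple[Interaction, Interaction]],
    measure: Callable | None = None,
    low: float = NEGATIVE_LOW,
    high: float = NEGATIVE_HIGH,
) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Negative_NN (four distinct families) and Negative_ND pairs with
    ``low`` < iiRMSD < ``high`` (both strict)."""
    if measure is None:
        measure = default_measure()

    def window(v: float | None) -> bool:
        return v is not None and low < v < high

    neg_nn: list[LabeledPair] = []
    for x, y in native_pairs:
        labels = {x.subunit_a.family_label, x.subunit_b.family_label,
                  y.subunit_a.family_label, y.subunit_b.family_label}
        if len(labels) < 4 or None in labels:
            continue
        v = measure(x, y)
        neg_nn.append(LabeledPair(x.id, y.id, v, "unrelated",
                                  "negative" if window(v) else "excluded"))
    neg_nd: list[LabeledPair] = []
    for x, y in decoy_pairs:
        v = measure(x, y)
        neg_nd.append(LabeledPair(x.id, y.id, v, "native-decoy",
                                  "negative" if window(v) else "excluded"))
    return neg_nn, neg_nd


def pairs_to_frame(pairs: Sequence[LabeledPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.id_1, p.id_2, p.iirmsd, p.relation, p.label) for p in pairs],
        columns=["id_1", "id_2", "iirmsd", "relation", "label"],
    )


# ---------------------------------------------------------------------------
# Distribution comparison

HISTOGRAM_RANGE = (0.0, 30.0)  # Angstrom
HISTOGRAM_BINS = 50


@dataclass
class Histogram:
    edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.masses = np.asarray(self.masses, float)
        if len(self.edges) != len(self.masses) + 1:
            raise ValueError("edges must be one longer than masses")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.masses)


def make_histogram(
    values: Sequence[float],
    n_bins: int = HISTOGRAM_BINS,
    value_range: tuple[float, float] = HISTOGRAM_RANGE,
) -> Histogram:
    """Equal-width histogram; values outside the range are clipped into
    the end bins."""
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if v.size == 0:
        raise ValueError("no values to histogram")
    lo, hi = value_range
    v = np.clip(v, lo, np.nextafter(hi, lo))
    counts, edges = np.histogram(v, bins=n_bins, range=value_range)
    return Histogram(edges, counts / counts.sum())


def bhattacharyya_distance(h1: Histogram, h2: Histogram) -> float:
    """d = sqrt(1 - sum_i sqrt(p_i q_i)), in [0, 1]."""
    if h1.n_bins != h2.n_bins or not np.allclose(h1.edges, h2.edges):
        raise ValueError("histograms must share the same binning")
    bc = float(np.sum(np.sqrt(h1.masses * h2.masses)))
    return float(np.sqrt(max(0.0, 1.0 - min(bc, 1.0))))
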