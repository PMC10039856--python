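"""Evaluation metrics: specificity, Shannon diversity, precision/recall/F1.

Specificity of a mode m in a cell group c is the squared-mean-normalized
share of the mode's activity attributable to that group:

    S(m, c) = a(m, c)^2 / sum_p a(m, p)^2

with a(m, c) the mean activity of m over the cells of c.  Rows sum to 1, so
S is directly comparable across modes; under a perfectly even activity the
expected value is 1/N, and a group is called *significantly* specific when
S is at least 50% above that expectation (S >= 1.5/N).

The Shannon Diversity Index of a cluster is its normalized identity entropy

    SDI = -sum_i p_i log(p_i) / log(N)

(0 = single identity, 1 = all N identities equally represented); it is used
to quantify how well clusters mix batches or patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .modes import ActivityMatrix

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class true positive / false positive / false negative counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SpecificityTable:
    """Mode x group specificity values plus the 1/N expectation."""

    table: pd.DataFrame  # modes x groups, rows sum to 1 (or 0 if undefined)
    expected_value: float

    @property
    def significant(self) -> pd.DataFrame:
        """Groups whose specificity is >= 50% above the 1/N expectation."""
        return self.table >= 1.5 * self.expected_value


def specificity(
    activity: ActivityMatrix | pd.DataFrame, groups: Sequence[str]
) -> SpecificityTable:
    """Specificity of every mode for every cell group.

    ``groups`` assigns one label (cluster or cell type) per cell.  A mode
    whose mean activity is zero in every group has an undefined ratio and
    yields a row of zeros with a warning.
    """
    frame = activity.to_frame() if isinstance(activity, ActivityMatrix) else activity
    groups = np.asarray(groups)
    if groups.shape[0] != frame.shape[1]:
        raise ValueError("one group label per cell is required")
    means = frame.T.groupby(groups).mean().T  # modes x groups
    sq = means**2
    denom = sq.sum(axis=1)
    dead = denom == 0
    if dead.any():
        warnings.warn(
            f"mode(s) {list(frame.index[dead])} have zero mean activity in every "
            "group; specificity undefined, returning zeros",
            stacklevel=2,
        )
    table = sq.div(denom.where(~dead, 1.0), axis=0)
    return SpecificityTable(table=table, expected_value=1.0 / means.shape[1])


def shannon_diversity(identities: Sequence, n_identities: int) -> float:
    """Normalized Shannon entropy of the identity composition of one cluster.

    ``n_identities`` is the number of possible identities N (patients,
    batches, ...); absent identities contribute 0.  Any logarithm base
    cancels in the ratio; natural log is used.
    """
    if n_identities < 2:
        raise ValueError("shannon_diversity requires N >= 2 (log N = 0 otherwise)")
    identities = list(identities)
    if not identities:
        raise ValueError("cluster is empty")
    counts = pd.Series(identities).value_counts()
    if counts.size > n_identities:
        raise ValueError(
            f"{counts.size} distinct identities observed but N={n_identities}"
        )
    p = counts.to_numpy(dtype=float) / len(identities)
    entropy = -float(np.sum(p * np.log(p)))
    return entropy / float(np.log(n_identities))


def mean_cluster_sdi(
    clusters: Sequence, identities: Sequence, n_identities: int
) -> float:
    """Mean Shannon Diversity Index over clusters."""
    clusters = np.asarray(clusters)
    identities = np.asarray(identities)
    if clusters.shape != identities.shape:
        raise ValueError("clusters and identities must align per cell")
    values = [
        shannon_diversity(identities[clusters == c], n_identities)
        for c in pd.unique(clusters)
    ]
    return float(np.mean(values))


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from confusion counts.

    Zero denominators (no predictions, no truth instances, or both P and R
    zero) yield 0 by convention, which keeps all-unassigned edge cases
    well-defined.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def per_class_confusion(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_map: Mapping[str, Sequence[str]],
    unassigned_label: str = UNASSIGNED,
) -> dict[str, ConfusionCounts]:
    """Confusion counts per truth class under a truth -> predicted-name map.

    ``class_map`` maps each truth class to the predicted names counted as
    correct (a truth class may map to several marker-list names).  An
    ``unassigned`` prediction is a false negative for its truth class and
    never a false positive for any class.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must align per cell")
    classes = list(pd.unique(pd.Series(truth)))
    missing = [t for t in classes if t not in class_map]
    if missing:
        raise ValueError(f"truth class(es) missing from class_map: {missing}")
    accept = {t: set(class_map[t]) for t in classes}
    tp = {t: 0 for t in classes}
    fp = {t: 0 for t in classes}
    fn = {t: 0 for t in classes}
    for t, p in zip(truth, predicted):
        if p in accept[t]:
            tp[t] += 1
            continue
        fn[t] += 1
        if p == unassigned_label:
            continue
        for other in classes:
            if other != t and p in accept[other]:
                fp[other] += 1
    return {t: ConfusionCounts(tp=tp[t], fp=fp[t], fn=fn[t]) for t in classes}


def per_class_scores(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_map: Mapping[str, Sequence[str]],
    unassigned_label: str = UNASSIGNED,
) -> pd.DataFrame:
    """Per-class precision/recall/F1 table (rows = truth classes)."""
    confusion = per_class_confusion(truth, predicted, class_map, unassigned_label)
    records = {}
    for cls, counts in confusion.items():
        p, r, f1 = precision_recall_f1(counts)
        records[cls] = {
            "precision": p,
            "recall": r,
            "f1": f1,
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
        }
    return pd.DataFrame.from_dict(records, orient="index")
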