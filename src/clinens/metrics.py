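"""Confusion-matrix classification metrics and ROC-AUC.

All metrics follow the standard definitions; any 0/0 cell yields an explicit
``None`` ("undefined") marker rather than NaN, so reports can render blanks
instead of silently propagating zeros.  F1 uses the 2TP/(2TP+FP+FN)
convention, which is 0 (not undefined) whenever there are true positives to
be found but none were predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricBundle:
    """Classification metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None


def _check_binary(v, name):
    v = np.asarray(v)
    if not np.isin(v, [0, 1]).all():
        raise ValueError(f"{name} contains values outside {{0,1}}")
    return v.astype(int)


def confusion(predictions, labels) -> ConfusionCounts:
    """Tabulate TP/FP/TN/FN for two equal-length binary vectors."""
    p = _check_binary(predictions, "predictions")
    y = _check_binary(labels, "labels")
    if len(p) != len(y):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(y)} labels")
    if len(p) == 0:
        raise ValueError("empty vectors")
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num, den):
    return num / den if den > 0 else None


def classification_metrics(counts: ConfusionCounts) -> MetricBundle:
    if counts.total <= 0:
        raise ValueError("no scored cases")
    return MetricBundle(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        f1=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    )


def auc(scores, labels) -> float:
    """Midrank ROC-AUC: P(score+ > score-) + 0.5 * P(tie).

    For a binary score this equals (sensitivity + specificity) / 2.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels, "labels")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0:
        raise ValueError("labels contain no positive class")
    if n0 == 0:
        raise ValueError("labels contain no negative class")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_rows(score_matrix, labels) -> np.ndarray:
    """Row-wise midrank AUC for a (B x n) score matrix against one label vector."""
    S = np.asarray(score_matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    r = rankdata(S, axis=1)
    return (r[:, y == 1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
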