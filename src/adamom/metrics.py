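"""Confusion-matrix construction and classification metrics.

Accuracy, precision, recall (sensitivity), specificity and F1 are all
derived from TP/FP/FN/TN tallies.  Multiclass predictions are tallied
one-vs-rest per class and summarized by micro-aggregation (summing the
per-class counts), which is the reading under which a single TP/FP/FN/TN
quadruple is well defined for a multiclass problem; macro (unweighted)
and support-weighted averages are also provided.  Zero-denominator
metrics raise :class:`UndefinedMetricError` rather than silently
returning 0, so a degenerate run cannot masquerade as a valid score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "confusion_from_predictions",
    "accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
    "macro_average",
    "weighted_average",
    "metrics_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Non-negative TP/FP/FN/TN tallies."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_from_predictions(
    predicted: np.ndarray,
    truth: np.ndarray,
    positive_class: object | None = None,
    multilabel: bool = False,
):
    """Tally confusion counts from predicted and true labels.

    * ``positive_class`` given: single binary tally with that class as
      positive.
    * class-index labels without ``positive_class``: dict of per-class
      one-vs-rest tallies (micro-aggregate by summing them).
    * ``multilabel=True`` with (n, L) 0/1 arrays: per-label tallies plus
      their micro sum, returned as (per_label list, micro).
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    if multilabel:
        if pred.ndim != 2:
            raise ValueError("multilabel mode expects (n, L) arrays")
        per_label = [
            _binary_counts(pred[:, l], true[:, l], 1) for l in range(pred.shape[1])
        ]
        micro = sum(per_label[1:], per_label[0])
        return per_label, micro
    if positive_class is not None:
        return _binary_counts(pred, true, positive_class)
    classes = np.unique(np.concatenate([pred.ravel(), true.ravel()]))
    return {c: _binary_counts(pred, true, c) for c in classes}


def _binary_counts(pred, true, positive) -> ConfusionCounts:
    p = pred == positive
    t = true == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined: zero denominator")
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP), the positive predictive value."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN), sensitivity."""
    return _ratio(c.tp, c.tp + c.fn, "recall")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall: 2PR / (P + R)."""
    p = precision(c)
    r = recall(c)
    if p + r == 0.0:
        raise UndefinedMetricError("f1 is undefined: precision + recall = 0")
    return 2.0 * p * r / (p + r)


def macro_average(per_class: dict, metric) -> float:
    """Unweighted mean of a metric over classes."""
    vals = [metric(c) for c in per_class.values()]
    return float(np.mean(vals))


def weighted_average(per_class: dict, metric) -> float:
    """Support-weighted (TP+FN per class) mean of a metric over classes."""
    supports = np.array([c.tp + c.fn for c in per_class.values()], dtype=float)
    if supports.sum() == 0:
        raise UndefinedMetricError("weighted average undefined: zero total support")
    vals = np.array([metric(c) for c in per_class.values()])
    return float(np.sum(vals * supports) / supports.sum())


def metrics_report(predicted, truth, multilabel: bool = False) -> pd.DataFrame:
    """Per-class + micro/macro/weighted metric table for a prediction set."""
    rows = []
    if multilabel:
        per_label, micro = confusion_from_predictions(predicted, truth, multilabel=True)
        per_class = {f"label_{l}": c for l, c in enumerate(per_label)}
        per_class["micro"] = micro
    else:
        ovr = confusion_from_predictions(predicted, truth)
        micro = sum(list(ovr.values())[1:], list(ovr.values())[0])
        per_class = {str(k): v for k, v in ovr.items()}
        per_class["micro"] = micro
    for name, c in per_class.items():
        row = {"class": name, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
        for metric in (accuracy, precision, recall, specificity, f1):
            try:
                row[metric.__name__] = metric(c)
            except UndefinedMetricError:
                row[metric.__name__] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
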