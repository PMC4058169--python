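"""Confusion-matrix metrics reported as percentages.

Accuracy, precision, recall and F-measure for two-class predictions with
labels in {+1, -1}.  The positive class defaults to the disease
("malignant") class of the clinical encoding, which this package maps to
-1; it is configurable because either class can be of clinical interest.
Degenerate denominators (no predicted positives / no true positives)
yield 0 with a warning rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "precision_recall_f",
    "classification_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: int = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_positive(self) -> "ConfusionCounts":
        """Counts with the opposite class treated as positive."""
        return ConfusionCounts(
            tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
            positive_label=-self.positive_label,
        )


def confusion(y_true, y_pred, positive_label: int = 1) -> ConfusionCounts:
    """Tally tp/fp/fn/tn for {+1, -1} label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    pos = positive_label
    return ConfusionCounts(
        tp=int(np.sum((y_true == pos) & (y_pred == pos))),
        fp=int(np.sum((y_true != pos) & (y_pred == pos))),
        fn=int(np.sum((y_true == pos) & (y_pred != pos))),
        tn=int(np.sum((y_true != pos) & (y_pred != pos))),
        positive_label=pos,
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(tp + tn) / n as a percentage."""
    if counts.n_evaluated == 0:
        raise ValueError("no evaluated samples")
    return 100.0 * (counts.tp + counts.tn) / counts.n_evaluated


def precision_recall_f(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F-measure, each in percent.

    precision = tp/(tp+fp), recall = tp/(tp+fn), F = 2PR/(P+R).
    An undefined ratio (zero denominator) is reported as 0 with a warning.
    """
    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
            return 0.0
        return 100.0 * num / den

    p = ratio(counts.tp, counts.tp + counts.fp, "precision")
    r = ratio(counts.tp, counts.tp + counts.fn, "recall")
    f = f_measure(p, r)
    return p, r, f


def f_measure(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean 2PR/(P+R) of precision/recall percentages."""
    if precision_pct + recall_pct == 0:
        warnings.warn("F-measure undefined (P + R = 0); reporting 0", stacklevel=3)
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def classification_report(y_true, y_pred, positive_label: int = 1) -> dict:
    """All four metrics in one pass, percentages keyed by name."""
    c = confusion(y_true, y_pred, positive_label)
    p, r, f = precision_recall_f(c)
    return {
        "accuracy": accuracy(c),
        "precision": p,
        "recall": r,
        "f_measure": f,
        "counts": c,
    }
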