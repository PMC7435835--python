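"""Per-minute classification metrics.

Apnea ('A') is the positive class throughout.  Accuracy, sensitivity and
specificity are reported in percent, rounded half-up to one decimal:

    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100%
    sensitivity = TP / (TP + FN) * 100%
    specificity = TN / (TN + FP) * 100%

ROC curves are computed over all distinct score thresholds and AUC by the
trapezoidal rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix", "confusion", "metrics", "roc_auc", "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (matching hand-reporting)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Event counts with apnea as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, "
                                 f"got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(labels: Sequence[str], predictions: Sequence[str]
              ) -> ConfusionMatrix:
    """Count TP/FP/TN/FN over paired true labels and predictions."""
    if len(labels) != len(predictions):
        raise ValueError(f"{len(labels)} labels vs {len(predictions)} "
                         "predictions")
    tp = fp = tn = fn = 0
    for lab, pred in zip(labels, predictions):
        if lab not in ("N", "A") or pred not in ("N", "A"):
            raise ValueError(f"labels must be 'N' or 'A', got ({lab!r}, "
                             f"{pred!r})")
        if lab == "A":
            if pred == "A":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "A":
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy/sensitivity/specificity in %, one decimal, half-up.

    A metric whose denominator is zero is reported as NaN and named in the
    ``undefined`` list rather than silently zeroed.
    """
    out: dict = {"undefined": []}
    pairs = {
        "accuracy": (cm.TP + cm.TN, cm.total),
        "sensitivity": (cm.TP, cm.TP + cm.FN),
        "specificity": (cm.TN, cm.TN + cm.FP),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = float("nan")
            out["undefined"].append(name)
        else:
            out[name] = round_half_up(100.0 * num / den, 1)
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[str]
            ) -> tuple[np.ndarray, float]:
    """ROC points over all distinct thresholds and trapezoidal AUC.

    ``scores`` are apnea-class probabilities (higher = more apneic).
    Returns an array of rows (fpr, tpr, threshold) and the AUC in [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == "A" else 0 for lab in labels])
    if len(scores) != len(y):
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thresh = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr, thresh]), auc
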