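"""Forecast evaluation: ROC AUC and the MCC-maximizing threshold panel.

Probability forecasts are summarized two ways: threshold-free, by the area
under the ROC curve, and at the single operating point that maximizes the
Matthews correlation coefficient (MCC), where the confusion counts,
sensitivity and specificity are reported alongside the MCC itself. MCC is

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention that a zero denominator factor yields MCC = 0.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from math import sqrt

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "roc_auc",
    "mcc",
    "confusion_at_threshold",
    "best_mcc_threshold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")


@dataclass(frozen=True)
class MetricsReport:
    """AUC plus the confusion panel at the MCC-maximizing threshold."""

    auc: float
    threshold: float
    confusion: ConfusionCounts
    sensitivity: float
    specificity: float
    mcc: float

    def to_dict(self, ndigits: int = 3) -> dict:
        c = self.confusion
        return {
            "tp": c.tp,
            "tn": c.tn,
            "fp": c.fp,
            "fn": c.fn,
            "auc": round(self.auc, ndigits),
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "mcc": round(self.mcc, ndigits),
            "threshold": self.threshold,
        }


def _check_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based area under the ROC curve, ties counted one half."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_both_classes(y)
    return float(roc_auc_score(y, p))


def mcc(confusion: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = confusion.tp, confusion.tn, confusion.fp, confusion.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)


def confusion_at_threshold(
    probabilities: Sequence[float], labels: Sequence[int], thr: float
) -> ConfusionCounts:
    """Counts when predicting positive iff probability >= ``thr``."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int).astype(bool)
    pred = p >= thr
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def best_mcc_threshold(
    probabilities: Sequence[float], labels: Sequence[int]
) -> MetricsReport:
    """Sweep all distinct operating points and report at the MCC maximum.

    Candidate thresholds are the midpoints between consecutive sorted unique
    probabilities, plus 0 and 1, so every achievable confusion matrix is
    visited; ties in MCC break toward the smallest threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_both_classes(y)
    uniq = np.unique(p)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))

    best_thr, best_mcc_val, best_conf = 0.0, -np.inf, None
    for thr in candidates:
        conf = confusion_at_threshold(p, y, thr)
        m = mcc(conf)
        if m > best_mcc_val:
            best_thr, best_mcc_val, best_conf = float(thr), m, conf
    return MetricsReport(
        auc=roc_auc(p, y),
        threshold=best_thr,
        confusion=best_conf,
        sensitivity=best_conf.sensitivity,
        specificity=best_conf.specificity,
        mcc=best_mcc_val,
    )
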