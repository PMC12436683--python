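"""Classifier evaluation: the five confusion-matrix metrics, ROC and AUC.

Positive class = glycated = 1.  Metrics with a zero denominator are reported
as 0 and flagged in :attr:`MetricsReport.undefined` rather than raising, so
repeat averaging stays total while remaining auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with class 1 (glycated) positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The five scalar metrics plus (optionally) AUC for one evaluation."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: Optional[float] = None
    n: int = 0
    undefined: frozenset = frozenset()

    def as_dict(self) -> Dict[str, float]:
        d = {
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass(frozen=True)
class RocCurve:
    """Staircase ROC: (FPR, TPR) points from (0,0) to (1,1)."""

    fpr: Tuple[float, ...]
    tpr: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fpr) != len(self.tpr) or len(self.fpr) < 2:
            raise ValueError("ROC curve needs matched FPR/TPR lists of length >= 2")
        if self.fpr[0] != 0.0 or self.tpr[0] != 0.0 or self.fpr[-1] != 1.0 or self.tpr[-1] != 1.0:
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


@dataclass
class RepeatSummary:
    """Per-metric mean and sample standard deviation over repeated runs."""

    mean: Dict[str, float]
    sd: Dict[str, float]
    n_repeats: int

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _validate_labels(labels: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(np.int64)


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """Confusion counts with class 1 positive; empty inputs give all zeros."""
    y = _validate_labels(true_labels, "true_labels")
    p = _validate_labels(predicted_labels, "predicted_labels")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} true vs {len(p)} predicted labels")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metric_suite(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and MCC from counts.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any ratio
    with a zero denominator is reported as 0 and flagged.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute metrics on zero evaluated examples")
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / n
    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.add("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(accuracy=accuracy, precision=precision,
                         sensitivity=sensitivity, specificity=specificity,
                         mcc=mcc, n=n, undefined=frozenset(undefined))


def roc_curve(true_labels: Sequence[int], positive_scores: Sequence[float]) -> RocCurve:
    """Threshold-sweep ROC over the glycation probabilities (ties grouped)."""
    y = _validate_labels(true_labels, "true_labels")
    s = np.asarray(positive_scores, dtype=np.float64)
    if len(y) != len(s):
        raise ValueError("labels and scores length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present in true_labels")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    # drop consecutive duplicate points introduced by the padding
    keep = np.concatenate([[True], (np.diff(fpr) != 0) | (np.diff(tpr) != 0)])
    fpr, tpr = fpr[keep], tpr[keep]
    return RocCurve(fpr=tuple(float(x) for x in fpr),
                    tpr=tuple(float(x) for x in tpr))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the staircase, in [0, 1]."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def aggregate_repeats(reports: Sequence[MetricsReport]) -> RepeatSummary:
    """Per-metric arithmetic mean and sample (n-1) sd over repeated runs.

    With a single report the sd is reported as 0.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report to aggregate")
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=np.float64)
        mean[name] = float(arr.mean())
        sd[name] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return RepeatSummary(mean=mean, sd=sd, n_repeats=len(reports))


def evaluate_predictions(true_labels: Sequence[int], probability_pairs: np.ndarray) -> MetricsReport:
    """Full report (incl. AUC) from ``(p_glycated, p_nonglycated)`` pairs."""
    pairs = np.asarray(probability_pairs, dtype=np.float64)
    preds = (pairs[:, 0] > pairs[:, 1]).astype(np.int64)
    report = metric_suite(confusion(true_labels, preds))
    report.auc = auc(roc_curve(true_labels, pairs[:, 0]))
    return report
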