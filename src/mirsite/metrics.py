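"""Confusion-based metrics, PR/ROC curves and imbalance arithmetic.

Under heavy class skew the area under the precision-recall curve
(auPRC) is the informative summary: unlike auROC it degrades as the
negative:positive ratio k grows, because precision mixes in the k-fold
larger false-positive pool.  The closed form

    precision(tpr, fpr, k) = tpr / (tpr + k * fpr)

makes that arithmetic explicit and links a scorer's class-conditional
rates to the precision it achieves at any ratio.

Conventions: a pair is predicted positive when score >= threshold (ties
count positive).  auPRC is non-interpolated average precision; auROC is
the trapezoidal area.  Quantities with zero denominators are returned
as NaN (the "undefined" flag) rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.FP + self.TN


@dataclass(frozen=True)
class Curve:
    """An ordered threshold curve with its area.

    ``x`` is recall (PR) or false-positive rate (ROC), non-decreasing;
    ``y`` is precision or true-positive rate; ``thresholds`` aligns with
    the points where defined.
    """

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    area: float
    kind: str  # "pr" | "roc"


@dataclass(frozen=True)
class ThresholdPolicy:
    """Operating thresholds: 'normal' for discovery, 'strict' for precision."""

    normal: float = 0.1
    strict: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.normal < self.strict < 1.0):
            raise ValueError("require 0 < normal < strict < 1")


def _as_hard_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.float64)
    hard = labels == 1.0
    soft = ~hard & (labels != 0.0)
    if soft.any():
        warnings.warn(
            f"{int(soft.sum())} soft label(s) thresholded at 0.5 for evaluation"
        )
        hard = labels > 0.5
    return hard.astype(np.int64)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with the predicted-positive rule score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    y = _as_hard_labels(labels).astype(bool)
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int((pred & y).sum()),
        FP=int((pred & ~y).sum()),
        TN=int((~pred & ~y).sum()),
        FN=int((~pred & y).sum()),
    )


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when there are no positives."""
    return c.TP / c.positives if c.positives else float("nan")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when nothing is predicted positive."""
    pred_pos = c.TP + c.FP
    return c.TP / pred_pos if pred_pos else float("nan")


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; NaN when undefined."""
    p, r = precision(c), recall(c)
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        return float("nan")
    return 2 * p * r / (p + r)


def precision_from_rates(tpr: float, fpr: float, k: float) -> float:
    """Precision implied by class-conditional rates at ratio 1:k.

    With P positives and kP negatives, TP = tpr*P and FP = fpr*kP, so
    precision = tpr / (tpr + k*fpr).  Returns 1 when fpr == 0 and tpr > 0,
    and NaN when tpr == fpr == 0 (nothing predicted positive).
    """
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise ValueError("tpr and fpr must lie in [0, 1]")
    if k <= 0:
        raise ValueError("k must be positive")
    if tpr == 0 and fpr == 0:
        return float("nan")
    if fpr == 0:
        return 1.0
    return tpr / (tpr + k * fpr)


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    y = _as_hard_labels(labels)
    if y.min() == y.max():
        raise ValueError("curves require at least one positive and one negative")
    return y


def pr_curve(scores, labels) -> Curve:
    """Precision-recall curve with non-interpolated average precision."""
    scores = np.asarray(scores, dtype=np.float64)
    y = _check_two_class(np.asarray(labels))
    prec, rec, thr = precision_recall_curve(y, scores)
    # sklearn returns recall decreasing; flip to non-decreasing order
    return Curve(
        x=rec[::-1],
        y=prec[::-1],
        thresholds=thr[::-1],
        area=float(average_precision_score(y, scores)),
        kind="pr",
    )


def roc_curve(scores, labels) -> Curve:
    """ROC curve with trapezoidal area."""
    scores = np.asarray(scores, dtype=np.float64)
    y = _check_two_class(np.asarray(labels))
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return Curve(
        x=fpr,
        y=tpr,
        thresholds=thr,
        area=float(roc_auc_score(y, scores)),
        kind="roc",
    )


def auprc(scores_or_curve, labels=None) -> float:
    """Area under the PR curve (average precision)."""
    if isinstance(scores_or_curve, Curve):
        return scores_or_curve.area
    return pr_curve(scores_or_curve, labels).area


def auroc(scores_or_curve, labels=None) -> float:
    """Area under the ROC curve (trapezoid)."""
    if isinstance(scores_or_curve, Curve):
        return scores_or_curve.area
    return roc_curve(scores_or_curve, labels).area


@dataclass
class EvalReport:
    """Threshold-level report plus curves for one scorer on one dataset."""

    rows: "object"  # pandas DataFrame: threshold, tag, TP, FP, TN, FN, precision, recall, f1
    pr: Curve | None = None
    roc: Curve | None = None
    auprc: float = float("nan")
    auroc: float = float("nan")


def threshold_report(
    scores,
    labels,
    policy: ThresholdPolicy = ThresholdPolicy(),
    grid: int = 99,
) -> "EvalReport":
    """Precision/recall/F1 at the 'normal' and 'strict' thresholds.

    Also tabulates a dense threshold grid for plotting, and attaches the
    PR/ROC curves and areas when both classes are present.
    """
    import pandas as pd

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    named = [(policy.normal, "normal"), (policy.strict, "strict")]
    dense = [(t, "grid") for t in np.linspace(0.01, 0.99, grid)]
    rows = []
    for thr, tag in named + dense:
        c = confusion(scores, labels, thr)
        rows.append(
            {
                "threshold": thr,
                "tag": tag,
                "TP": c.TP,
                "FP": c.FP,
                "TN": c.TN,
                "FN": c.FN,
                "precision": precision(c),
                "recall": recall(c),
                "f1": f1(c),
            }
        )
    report = EvalReport(rows=pd.DataFrame(rows))
    y = _as_hard_labels(labels)
    if y.size and y.min() != y.max():
        report.pr = pr_curve(scores, labels)
        report.roc = roc_curve(scores, labels)
        report.auprc = report.pr.area
        report.auroc = report.roc.area
    return report
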