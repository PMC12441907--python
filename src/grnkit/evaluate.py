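"""Confusion-matrix metrics, ROC/AUC and stratified cross-validation.

Accuracy, precision, recall (sensitivity), specificity and F1 are computed
directly from confusion counts at a fixed score threshold (0.5 by default).
Ratios with a zero denominator are reported as ``None`` with a warning,
never silently coerced to 0. The ROC curve sweeps thresholds over the
unique scores; its trapezoidal area equals the Mann-Whitney concordance
probability with half credit for ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger("grnkit")

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
    "f1_score_at",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "ConfusionCounts":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if scores.shape != labels.shape:
            raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ in length")
        pred = scores >= threshold
        pos = labels == 1
        return cls(
            tp=int(np.sum(pred & pos)),
            fp=int(np.sum(pred & ~pos)),
            tn=int(np.sum(~pred & ~pos)),
            fn=int(np.sum(~pred & pos)),
        )


@dataclass
class MetricsReport:
    """Threshold-dependent metrics; undefined ratios are None (flagged)."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]
    auc: Optional[float]
    threshold: float
    counts: Optional[ConfusionCounts] = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "threshold": self.threshold,
        }


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as None")
        return None
    return num / den


def metrics_from_counts(c: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Apply the five confusion-count formulas verbatim."""
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    if precision is None or recall is None or precision + recall == 0:
        warnings.warn("f1 undefined; reported as None")
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy, precision, recall, specificity, f1, None, threshold, c)


def confusion_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Threshold the scores at ``threshold`` and report the five metrics."""
    return metrics_from_counts(ConfusionCounts.from_scores(scores, labels, threshold), threshold)


def f1_score_at(scores, labels, threshold: float = 0.5) -> Optional[float]:
    return confusion_metrics(scores, labels, threshold).f1


@dataclass
class ROCCurve:
    """(FPR, TPR) points over score thresholds plus the trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be monotone non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC by descending-threshold sweep over unique scores.

    Tied scores collapse into a single curve point, so the trapezoidal area
    equals the rank-sum (Mann-Whitney) concordance with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each distinct threshold (last index of each tie group)
    distinct = np.flatnonzero(np.r_[np.diff(s) != 0, True])
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thresholds, auc)


def cross_validate(model_spec, X, y, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified k-fold CV accuracies; each row is scored exactly once.

    ``model_spec`` is a :class:`~grnkit.models.ClassifierSpec` or any object
    with scikit-learn ``fit``/``predict``. Fold assignment is reproducible
    for a fixed seed.
    """
    from .models import ClassifierSpec, make_classifier
    from sklearn.base import clone

    X = np.asarray(X)
    y = np.asarray(y).ravel()
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2:
        raise ValueError("cross-validation requires both classes")
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds minority class size {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        if isinstance(model_spec, ClassifierSpec):
            est = make_classifier(model_spec)
        else:
            est = clone(model_spec)
        est.fit(X[tr], y[tr])
        scores.append(float((est.predict(X[te]) == y[te]).mean()))
    return np.asarray(scores)
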