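"""Confusion counts, threshold metrics, ROC/AUROC and fold aggregation.

Conventions: albinism (label 1) is the positive class; a sample is
predicted positive iff score >= threshold; undefined metrics are reported
as NaN markers and excluded (with a logged count) from fold averages,
never silently coerced to zero. Fold standard deviations are population
standard deviations (divide by k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError

UNDEFINED = float("nan")

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity", "auroc")


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN; fractional values allowed (fold-averaged matrices)."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float = UNDEFINED
    precision: float = UNDEFINED
    recall: float = UNDEFINED
    f1: float = UNDEFINED
    specificity: float = UNDEFINED
    auroc: float = UNDEFINED

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending; leading +inf sentinel
    tpr: np.ndarray
    fpr: np.ndarray


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError(f"scores {scores.shape} and labels {labels.shape} must be equal-length 1-D")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValidationError("labels must be 0/1")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    return scores, labels


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts with 'predicted positive iff score >= threshold'."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=float(np.sum(pred & pos)),
        fp=float(np.sum(pred & ~pos)),
        fn=float(np.sum(~pred & pos)),
        tn=float(np.sum(~pred & ~pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy/precision/recall/F1 from counts; zero denominators yield NaN."""
    if counts.total <= 0:
        raise ValidationError("all-zero confusion counts")
    return MetricsReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        recall=_ratio(counts.tp, counts.tp + counts.fn),
        f1=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
    )


def roc_and_auroc(scores, labels):
    """ROC over all distinct-score thresholds plus a +inf sentinel.

    AUROC is the trapezoidal area, which for this construction equals the
    Mann-Whitney statistic with ties counted 1/2.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[True, np.diff(s) != 0]
    cum_tp = np.cumsum(y == 1)
    cum_fp = np.cumsum(y == 0)
    # counts *at* each threshold = cumulative counts at the last tied position
    last_of_run = np.r_[distinct[1:], True]
    thresholds = np.r_[np.inf, s[distinct]]
    tpr = np.r_[0.0, cum_tp[last_of_run] / n_pos]
    fpr = np.r_[0.0, cum_fp[last_of_run] / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, tpr, fpr), auroc


def optimal_threshold(roc: ROCCurve) -> float:
    """Youden: maximize tpr - fpr; ties broken toward the highest threshold.

    Each ROC operating point is realized by the midpoint between the adjacent
    distinct scores (any threshold in that open-closed interval yields the
    same confusion counts; the midpoint transfers best to unseen data). The
    degenerate "predict nothing positive" point returns +inf.
    """
    j = roc.tpr - roc.fpr
    best = np.max(j)
    idx = int(np.argmax(j == best))  # first (= highest-threshold / fewest-positives) maximizer
    d = roc.thresholds
    if idx == 0:
        return float("inf")
    if idx < len(d) - 1:
        return float((d[idx] + d[idx + 1]) / 2.0)
    return float(d[idx])  # lowest distinct score: every sample predicted positive


def evaluate_scores(scores, labels, threshold: float):
    """(ConfusionCounts, MetricsReport incl. AUROC) at a fixed threshold."""
    counts = confusion_at_threshold(scores, labels, threshold)
    report = compute_metrics(counts)
    try:
        _, auroc = roc_and_auroc(scores, labels)
        report.auroc = auroc
    except UndefinedMetricError:
        report.auroc = UNDEFINED
    return counts, report


@dataclass
class FoldAggregate:
    mean: dict
    sd: dict
    n_defined: dict
    confusion: ConfusionCounts
    n_folds: int


def aggregate_folds(per_fold) -> FoldAggregate:
    """Average (ConfusionCounts, MetricsReport) pairs across folds.

    Metric means/population-sds skip undefined (NaN) fold values, logging how
    many folds were defined; confusion cells are averaged arithmetically and
    may be fractional.
    """
    per_fold = list(per_fold)
    if not per_fold:
        raise ValidationError("no folds to aggregate")
    mean, sd, n_defined = {}, {}, {}
    for name in METRIC_NAMES:
        values = np.array([getattr(rep, name) for _, rep in per_fold], dtype=float)
        defined = values[~np.isnan(values)]
        n_defined[name] = int(defined.size)
        if defined.size:
            mean[name] = float(defined.mean())
            sd[name] = float(defined.std())  # population sd over folds
        else:
            mean[name] = UNDEFINED
            sd[name] = UNDEFINED
    confusion = ConfusionCounts(
        tp=float(np.mean([c.tp for c, _ in per_fold])),
        fp=float(np.mean([c.fp for c, _ in per_fold])),
        fn=float(np.mean([c.fn for c, _ in per_fold])),
        tn=float(np.mean([c.tn for c, _ in per_fold])),
    )
    return FoldAggregate(mean, sd, n_defined, confusion, len(per_fold))


def as_percent(fraction: float) -> float:
    """Rounded integer percent, NaN-propagating (mirrors the summary tables)."""
    if math.isnan(fraction):
        return UNDEFINED
    return float(round(fraction * 100))
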