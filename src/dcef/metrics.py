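"""Binary-classification metrics: confusion-matrix rates, ROC, and AUC.

Malignant is the positive class (label 1). The five threshold metrics are
the standard confusion-matrix rates

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)

plus balanced accuracy, the mean of sensitivity and specificity. AUC is
computed from the rank statistic (Mann-Whitney pairwise concordance, ties
counted half), which equals the trapezoidal area under the ROC curve; the
test suite checks the two routes against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "balanced_accuracy",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if sum(counts) < 1:
            raise ValueError("need at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ScoredPredictions:
    """Malignancy scores in [0, 1] with ground-truth binary labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels).astype(int)
        if s.ndim != 1 or s.shape != y.shape:
            raise ValueError("scores and labels must be equal-length vectors")
        if s.size == 0:
            raise ValueError("empty predictions")
        if np.any((s < 0) | (s > 1)) or not np.all(np.isfinite(s)):
            raise ValueError("scores must lie in [0, 1]")
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("labels must be binary")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    @property
    def n(self) -> int:
        return self.scores.size


def confusion(scored: ScoredPredictions, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold the scores (>= threshold means predicted positive)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    pred = scored.scores >= threshold
    pos = scored.labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


@dataclass(frozen=True)
class MetricReport:
    """Metric values; any metric with a zero denominator is NaN and flagged."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    balanced_accuracy: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """All six rates from one confusion matrix.

    A metric whose denominator is zero (e.g. precision with no positive
    predictions) is reported as NaN and listed in ``undefined`` rather than
    silently coerced to 0.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    values = {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "sensitivity": sens,
        "specificity": spec,
        "precision": _ratio(c.tp, c.tp + c.fp),
        "f1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "balanced_accuracy": (sens + spec) / 2.0,
    }
    undefined = frozenset(k for k, v in values.items() if math.isnan(v))
    return MetricReport(**values, undefined=undefined)


def roc_auc(scored: ScoredPredictions) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    AUC is the Mann-Whitney concordance: the probability that a random
    positive outscores a random negative, with ties counted half — computed
    from average ranks. The ROC points (FPR, TPR) sweep every distinct
    score threshold. Requires both classes present.
    """
    pos = scored.labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC/AUC")
    ranks = rankdata(scored.scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(scored.labels, scored.scores)
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


def youden_threshold(scored: ScoredPredictions) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1."""
    fpr, tpr, thresholds = _sk_roc_curve(scored.labels, scored.scores)
    best = np.argmax(tpr - fpr)
    return float(np.clip(thresholds[best], 0.0, 1.0))
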