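"""Per-combination performance measures.

Binary gene-trait combinations are scored by the area under the balanced
precision-recall curve (AUBPRC); quantitative combinations by the squared
Pearson correlation (PCC²) between oriented variant scores and variant-mean
trait values.

Balanced precision is the precision expected in an evaluation set with a
50% prior on positives: TPR / (TPR + FPR).  Unlike raw precision it is
invariant to trait prevalence, which varies wildly between phenotypes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import UndefinedMetricError

__all__ = [
    "ThresholdedConfusion",
    "confusion_at_threshold",
    "balanced_precision",
    "bprc_curve",
    "aubprc",
    "squared_pearson",
]


@dataclass(frozen=True)
class ThresholdedConfusion:
    """Confusion counts for the rule `predict positive iff score >= threshold`."""

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    @property
    def pp(self) -> int:
        return self.tp + self.fp


def confusion_at_threshold(scores, labels, threshold: float) -> ThresholdedConfusion:
    """Count TP/FP/FN/TN for participants called positive at ``score >= threshold``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return ThresholdedConfusion(threshold, tp, fp, fn, tn)


def balanced_precision(c: ThresholdedConfusion) -> float:
    """Precision under a rebalanced 50% prior: TPR / (TPR + FPR).

    Undefined when the evaluation set lacks a class, or at thresholds where
    nothing is predicted positive (TP = FP = 0); the curve builder handles the
    latter by anchoring, so this function raises for both.
    """
    if c.p == 0 or c.n == 0:
        raise UndefinedMetricError("balanced precision needs both classes present")
    if c.pp == 0:
        raise UndefinedMetricError(
            "balanced precision is 0/0 when no participant is predicted positive"
        )
    tpr = c.tp / c.p
    fpr = c.fp / c.n
    return tpr / (tpr + fpr)


def bprc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Balanced precision-recall curve over all distinct score thresholds.

    Thresholds are the distinct observed scores in descending order; tied
    participants move across thresholds together.  A recall-0 anchor extends
    the balanced precision of the most stringent achieved threshold; the
    minimal threshold always reaches recall 1.

    Returns (recall, balanced_precision) arrays, recall non-decreasing.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.size == 0:
        raise UndefinedMetricError("empty evaluation set")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUBPRC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    # index of the last member of each tie group = achieved thresholds
    last = np.flatnonzero(np.r_[ss[1:] != ss[:-1], True])
    tp = np.cumsum(ys)[last]
    pp = last + 1.0
    fp = pp - tp
    tpr = tp / n_pos
    fpr = fp / n_neg
    # pp >= 1 at every achieved threshold, so tpr + fpr > 0 always
    bp = tpr / (tpr + fpr)
    recall = np.r_[0.0, tpr]
    bprec = np.r_[bp[0], bp]
    return recall, bprec


def aubprc(scores, labels) -> float:
    """Area under the balanced precision-recall curve, trapezoidal over recall.

    Invariant under strictly increasing transforms of the scores; 1.0 for
    perfectly separating scores; 0.5 in expectation for uninformative ones.
    """
    recall, bprec = bprc_curve(scores, labels)
    return float(np.trapezoid(bprec, recall))


def squared_pearson(x, y) -> float:
    """Square of the Pearson correlation of paired observations.

    Squaring weights positive and negative correlations of equal strength
    equally, which matters because a predictor's orientation is arbitrary
    relative to the direction a damaging variant shifts a quantitative trait.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise UndefinedMetricError("PCC² needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("PCC² undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
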