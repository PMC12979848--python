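"""Classification metrics for link prediction, computed internally.

ROC/PR and threshold metrics are implemented directly (rank statistics and
explicit threshold sweeps) so that correctness-critical numbers carry no
external ML dependency; the test suite cross-checks them against
scikit-learn on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) statistic.

    Ties in the scores contribute 1/2, matching the trapezoidal ROC area.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same shape")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative label")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


@dataclass
class ThresholdMetrics:
    threshold: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


def threshold_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ThresholdMetrics:
    """Precision/recall/F1/accuracy at one decision threshold (ties -> 1)."""
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(labels)
    return ThresholdMetrics(threshold, precision, recall, f1, accuracy, tp, fp, tn, fn)


def roc_curve_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points from a sweep over every distinct score threshold."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    fpr, tpr = [], []
    for t in thresholds:
        pred = scores >= t
        tpr.append(np.sum(pred & (labels == 1)) / n_pos)
        fpr.append(np.sum(pred & (labels == 0)) / n_neg)
    return np.asarray(fpr), np.asarray(tpr)
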