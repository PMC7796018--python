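"""Detection and classification metrics.

ROC/AUC over a sweep of all distinct score thresholds (TPR = TP/(TP+FN),
FPR = FP/(FP+TN), trapezoidal area), and unweighted macro-averaged
precision/recall/F-measure plus plain accuracy for multi-class output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # score cut-offs matching fpr/tpr from index 1 on
    auc: float

    def __post_init__(self) -> None:
        if not (self.fpr[0] == 0.0 and self.tpr[0] == 0.0):
            raise ValueError("ROC must start at (0, 0)")
        if not (np.isclose(self.fpr[-1], 1.0) and np.isclose(self.tpr[-1], 1.0)):
            raise ValueError("ROC must end at (1, 1)")
        if np.any(np.diff(self.fpr) < 0):
            raise ValueError("FPR must be non-decreasing")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class MacroMetrics:
    precision: float
    recall: float
    f_measure: float
    accuracy: float


def roc_curve(scores, truth_flags) -> ROCResult:
    """ROC over all distinct score thresholds; AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_flags, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth_flags must be equal-length 1-D")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative instance")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    # threshold at every distinct score: include all instances scoring >= it
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    cut = np.concatenate([distinct, [len(scores) - 1]])
    tp = np.cumsum(sorted_truth)[cut]
    fp = np.cumsum(~sorted_truth)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=sorted_scores[cut], auc=auc)


def macro_metrics(predicted_labels, true_labels, n_classes: int) -> MacroMetrics:
    """Unweighted per-class precision/recall average, F, and accuracy.

    A class with no predicted instances contributes 0 to macro precision
    (likewise recall for a class with no true instances).
    """
    pred = np.asarray(predicted_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("label arrays must be equal-length 1-D")
    if pred.size == 0:
        raise ValueError("no instances")
    if np.any((pred < 0) | (pred >= n_classes)) or np.any((true < 0) | (true >= n_classes)):
        raise ValueError("labels out of range")
    precisions = []
    recalls = []
    tp_total = 0
    for c in range(n_classes):
        tp = int(np.sum((pred == c) & (true == c)))
        inferred = int(np.sum(pred == c))
        actual = int(np.sum(true == c))
        precisions.append(tp / inferred if inferred else 0.0)
        recalls.append(tp / actual if actual else 0.0)
        tp_total += tp
    precision = float(np.mean(precisions))
    recall = float(np.mean(recalls))
    f_measure = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MacroMetrics(
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        accuracy=tp_total / pred.size,
    )
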