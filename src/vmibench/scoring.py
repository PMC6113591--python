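"""ROC/AUC scoring of a predicted network against the true network.

A correlation network R is turned into binary predictions by thresholding at
every distinct observed value c (entries >= c predict "interaction"); the
resulting true-positive and false-positive rates trace the ROC, and the area
under it (trapezoidal) summarizes predictive power: 1 is perfect, 1/2 is
uninformative, below 1/2 means interactions and noninteractions are being
classified the opposite way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import CorrelationNetwork

__all__ = ["ROCResult", "binarize_truth", "roc_auc", "auc_rank"]


@dataclass
class ROCResult:
    thresholds: np.ndarray   # descending, with sentinels beyond the extremes
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def binarize_truth(weighted: np.ndarray) -> np.ndarray:
    """Boolean truth from a weighted interaction network (positive -> 1).

    Degenerate truths (all ones or all zeros) are rejected: both TPR and
    FPR need a nonempty class.
    """
    W = np.asarray(weighted)
    if (W < 0).any():
        raise ValueError("interaction weights must be nonnegative")
    truth = W > 0
    if truth.all() or not truth.any():
        raise ValueError("truth must contain at least one interaction and "
                         "one noninteraction")
    return truth


def roc_auc(R: CorrelationNetwork | np.ndarray, truth: np.ndarray) -> ROCResult:
    """Threshold sweep over the distinct values of R, trapezoidal AUC.

    Scores >= c are predicted interactions.  Thresholds are the observed
    score values plus sentinels below the minimum and above the maximum, so
    the ROC always starts at (0, 0) and ends at (1, 1) regardless of the
    score range (LS scores are not confined to [-1, 1]).
    """
    scores = np.asarray(R.R if isinstance(R, CorrelationNetwork) else R,
                        dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("score and truth shapes disagree")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth needs at least one positive and one negative")

    s = scores.ravel()
    y = truth.ravel()
    values = np.unique(s)
    thresholds = np.concatenate([[values[-1] + 1.0], values[::-1],
                                 [values[0] - 1.0]])
    tp = np.array([(y & (s >= c)).sum() for c in thresholds], dtype=float)
    fp = np.array([(~y & (s >= c)).sum() for c in thresholds], dtype=float)
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def auc_rank(R: CorrelationNetwork | np.ndarray, truth: np.ndarray) -> float:
    """AUC via the tie-corrected rank statistic (Mann-Whitney form).

    Independent of the threshold sweep; with ties handled by midranks the
    two formulations agree exactly, which the test suite exploits.
    """
    from scipy.stats import rankdata

    scores = np.asarray(R.R if isinstance(R, CorrelationNetwork) else R,
                        dtype=float).ravel()
    y = np.asarray(truth, dtype=bool).ravel()
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
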