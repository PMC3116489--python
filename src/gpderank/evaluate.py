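"""ROC curves and AUC for a differential-expression ranking.

The ROC curve sweeps score thresholds from high to low and plots the false
positive rate against the true positive rate; its area equals the
probability that a random positive outranks a random negative (ties count
one half), i.e. the Mann-Whitney U statistic normalised by the number of
positive-negative pairs.  Both routes are provided: the curve (trapezoidal
area) and the rank-statistic ``auc``, which agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ROCCurve", "roc_curve", "auc"]


@dataclass(frozen=True)
class ROCCurve:
    """ROC sweep: monotone fpr/tpr from (0,0) to (1,1), thresholds, area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve over descending unique score thresholds, ties grouped.

    ``-inf`` sentinel scores are admissible (they sort below every finite
    score).  The area is the trapezoidal integral of tpr over fpr.
    """
    s, y = _check_inputs(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=area)


def auc(scores, labels) -> float:
    """AUC by the Mann-Whitney rank statistic (tied pairs credit 1/2).

    Equals ``roc_curve(scores, labels).auc`` to machine precision and is
    invariant under strictly monotone transforms of the scores.
    """
    s, y = _check_inputs(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    # midranks handle ties with the 1/2 convention; -inf sentinels rank lowest
    r = rankdata(s, method="average")
    u = float(r[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
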