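"""Classification metrics and the paired significance test.

Accuracy and F1 follow the confusion-matrix formulas
ACC = (TP+TN)/(TP+FN+FP+TN), PPV = TP/(TP+FP), SEN = TP/(TP+FN),
F1 = 2 PPV SEN / (PPV + SEN), with the positive class +1 and predicted
labels taken from the sign of the decision score (score 0 -> +1).  AUC is
the rank-based probability that a random positive's score exceeds a
random negative's, ties counting one half — invariant under any strictly
monotone score transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import DataError, DegenerateTestError

__all__ = ["EvalReport", "compute_metrics", "paired_ttest"]


@dataclass
class EvalReport:
    """Per-fold evaluation summary of one held-out subject."""

    subject: str
    tp: int
    fn: int
    fp: int
    tn: int
    acc: float
    f1: float
    auc: Optional[float]
    mean_u: Optional[np.ndarray] = None
    chosen_C: Optional[float] = None
    chosen_tau: Optional[float] = None

    @property
    def n_test(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def compute_metrics(scores: Sequence[float], labels: Sequence[int],
                    subject: str = "") -> EvalReport:
    """Confusion counts, ACC, F1 and AUC from scores and true labels.

    AUC is undefined when only one class is present; it is then reported
    as None with a warning rather than raising, since single-class test
    folds legitimately occur.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.size == 0:
        raise DataError("scores and labels must be equal-length and nonempty")
    if not set(np.unique(labels)) <= {-1, 1}:
        raise DataError("labels must be +1 / -1")
    pred = np.where(scores >= 0, 1, -1)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == -1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == -1)))
    tn = int(np.sum((pred == -1) & (labels == -1)))
    acc = (tp + tn) / scores.size
    ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * ppv * sen / (ppv + sen) if ppv + sen > 0 else 0.0
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined for single-class labels; reported as None")
        auc: Optional[float] = None
    else:
        auc = float(roc_auc_score((labels == 1).astype(int), scores))
    return EvalReport(subject=subject, tp=tp, fn=fn, fp=fp, tn=tn,
                      acc=acc, f1=f1, auc=auc)


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed paired t-test on per-subject metric vectors.

    Returns ``(t, p)``.  All-zero differences make the test undefined and
    raise; zero-variance differences with nonzero mean (a constant shift)
    yield an infinite t and p = 0 with a warning, which is the sensible
    limit rather than an error.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise DataError("paired test needs equal-length vectors of length >= 2")
    d = a - b
    if np.allclose(d, 0.0):
        raise DegenerateTestError("all paired differences are zero")
    if np.ptp(d) == 0.0:
        warnings.warn("zero-variance nonzero paired differences: p reported as 0")
        return (np.inf if d[0] > 0 else -np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
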