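"""Nuclear-norm-regularized hinge-loss matrix classifier.

The classifier operates directly on the (J+1) x d feature matrix Zhat.
With regression matrix W, bias b, trade-off C > 0 and nuclear penalty
tau >= 0, the training objective over N samples is

    (1/2) ||W||_F^2  +  tau ||W||_*  +  C sum_i max(0, 1 - y_i (<W, Zhat_i> + b))

where <W, Z> = trace(W^T Z) and ||W||_* is the sum of singular values —
the convex surrogate of rank.  Penalizing it pulls W toward low rank, so
the decision rule is forced to exploit correlated structure across the
stacked region rows instead of treating them independently.

The nuclear term is non-smooth; SGD uses its standard subgradient
U V^T from the thin SVD (restricted to numerically nonzero singular
values).  Samples sitting exactly on the margin contribute nothing
(a valid subgradient choice, and deterministic).  Prediction is the sign
of trace(W^T Zhat) + b, with score 0 mapped to +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .exceptions import ConfigError, DataError, ShapeError

__all__ = [
    "MatrixClassifier",
    "nuclear_norm",
    "nuclear_subgradient",
    "hinge_loss",
    "objective",
    "objective_gradients",
    "predict",
    "effective_rank",
]

SVD_TOL_FACTOR = 1e-10  # singular values below this fraction of the largest are rank noise


@dataclass
class MatrixClassifier:
    """Regression matrix W, bias b and the objective hyperparameters."""

    W: np.ndarray
    b: float = 0.0
    C: float = 1.0
    tau: float = 1e-2

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ShapeError("W must be a matrix")
        if not np.isfinite(self.W).all():
            raise DataError("non-finite entries in W")
        if self.C <= 0:
            raise ConfigError(f"C must be positive, got {self.C}")
        if self.tau < 0:
            raise ConfigError(f"tau must be nonnegative, got {self.tau}")


def nuclear_norm(W: np.ndarray) -> float:
    """Sum of singular values of W (the ||W||_* factor, without tau)."""
    W = np.asarray(W, dtype=np.float64)
    if not np.isfinite(W).all():
        raise DataError("non-finite entries in W")
    return float(np.linalg.svd(W, compute_uv=False).sum())


def nuclear_subgradient(W: np.ndarray) -> np.ndarray:
    """Subgradient U V^T of the nuclear norm at W (tau-free).

    Thin SVD restricted to singular values above ``SVD_TOL_FACTOR`` times
    the largest; at W = 0 the zero matrix is returned (a valid element of
    the subdifferential).  Where W has full rank with distinct nonzero
    singular values this is the exact gradient.
    """
    W = np.asarray(W, dtype=np.float64)
    if not np.isfinite(W).all():
        raise DataError("non-finite entries in W")
    U, svals, Vt = np.linalg.svd(W, full_matrices=False)
    if svals.size == 0 or svals[0] == 0.0:
        return np.zeros_like(W)
    keep = svals > SVD_TOL_FACTOR * svals[0]
    return U[:, keep] @ Vt[keep, :]


def _score(Zhat: np.ndarray, clf: MatrixClassifier) -> float:
    Zhat = np.asarray(Zhat, dtype=np.float64)
    if Zhat.shape != clf.W.shape:
        raise ShapeError(
            f"feature matrix shape {Zhat.shape} does not match W {clf.W.shape}"
        )
    return float(np.sum(clf.W * Zhat) + clf.b)


def hinge_loss(Zhat: np.ndarray, y: int, clf: MatrixClassifier) -> float:
    """max(0, 1 - y (trace(W^T Zhat) + b)) for one sample."""
    if y not in (-1, 1):
        raise DataError(f"label must be +1 or -1, got {y}")
    return max(0.0, 1.0 - y * _score(Zhat, clf))


def objective(batch: Sequence[Tuple[np.ndarray, int]], clf: MatrixClassifier) -> float:
    """Full objective (1/2)||W||_F^2 + tau ||W||_* + C sum hinge."""
    if len(batch) == 0:
        raise DataError("objective needs a nonempty batch")
    reg = 0.5 * float(np.sum(clf.W ** 2)) + clf.tau * nuclear_norm(clf.W)
    return reg + clf.C * sum(hinge_loss(Z, y, clf) for Z, y in batch)


def objective_gradients(batch: Sequence[Tuple[np.ndarray, int]],
                        clf: MatrixClassifier) -> Tuple[np.ndarray, float]:
    """(subgradient w.r.t. W, gradient w.r.t. b) of :func:`objective`.

    Margin-violating samples (hinge > 0) contribute -C y_i Zhat_i to the
    W gradient and -C y_i to the b gradient; samples at or beyond the
    margin contribute nothing.
    """
    if len(batch) == 0:
        raise DataError("gradient needs a nonempty batch")
    gW = clf.W + clf.tau * nuclear_subgradient(clf.W)
    gb = 0.0
    for Zhat, y in batch:
        if hinge_loss(Zhat, y, clf) > 0.0:
            gW = gW - clf.C * y * np.asarray(Zhat, dtype=np.float64)
            gb -= clf.C * y
    return gW, gb


def predict(Zhat: np.ndarray, clf: MatrixClassifier) -> Tuple[float, int]:
    """(score, label): score = trace(W^T Zhat) + b, label = sign (0 -> +1)."""
    score = _score(Zhat, clf)
    return score, (1 if score >= 0 else -1)


def effective_rank(W: np.ndarray, rel_threshold: float = 0.01) -> int:
    """Number of singular values >= ``rel_threshold`` times the largest."""
    svals = np.linalg.svd(np.asarray(W, dtype=np.float64), compute_uv=False)
    if svals.size == 0 or svals[0] == 0.0:
        return 0
    return int(np.sum(svals >= rel_threshold * svals[0]))
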