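"""Squeeze-and-excitation region attention and feature-matrix stacking.

The J per-region feature vectors plus the global one are treated as J+1
channels of a feature map.  A squeeze step averages each vector to a
channel statistic s_j; a two-layer gating network (ReLU then sigmoid, no
biases) maps s to a weight vector u in (0,1)^(J+1); scaling each feature
vector by its weight and stacking rows gives the feature matrix Zhat that
the matrix classifier consumes.  The hidden width is
``max(1, floor((J+1)/r))`` with reduction ratio r (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .exceptions import ConfigError, ShapeError

__all__ = [
    "attention_hidden_width",
    "init_attention_params",
    "squeeze",
    "excite",
    "scale_and_stack",
    "attention_forward",
    "attention_backward",
]


def attention_hidden_width(n_channels: int, r: int = 2) -> int:
    """Bottleneck width: floor((J+1)/r), at least 1."""
    if n_channels < 1 or r < 1:
        raise ConfigError("need n_channels >= 1 and r >= 1")
    return max(1, n_channels // r)


def init_attention_params(n_channels: int, r: int,
                          rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Glorot-uniform gating weights W1 (hidden x J+1) and W2 (J+1 x hidden)."""
    hidden = attention_hidden_width(n_channels, r)
    lim1 = np.sqrt(6.0 / (n_channels + hidden))
    lim2 = np.sqrt(6.0 / (hidden + n_channels))
    return {
        "W1": rng.uniform(-lim1, lim1, (hidden, n_channels)),
        "W2": rng.uniform(-lim2, lim2, (n_channels, hidden)),
    }


def squeeze(Z: np.ndarray) -> np.ndarray:
    """Channel statistics: s_j = mean over the feature axis of z_j.

    ``Z`` is (J+1, d) for one sample or (N, J+1, d) for a batch; the
    result drops the last axis.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim not in (2, 3):
        raise ShapeError("squeeze expects (J+1, d) or (N, J+1, d)")
    if not np.isfinite(Z).all():
        raise ShapeError("non-finite feature values")
    return Z.mean(axis=-1)


def excite(s: np.ndarray, params: Dict[str, np.ndarray]) -> np.ndarray:
    """Gating: u = sigmoid(W2 . relu(W1 . s)); every entry in (0, 1)."""
    s = np.asarray(s, dtype=np.float64)
    W1, W2 = params["W1"], params["W2"]
    if s.shape[-1] != W1.shape[1]:
        raise ShapeError(
            f"statistics length {s.shape[-1]} does not match W1 columns {W1.shape[1]}"
        )
    h = np.maximum(s @ W1.T, 0.0)
    return 1.0 / (1.0 + np.exp(-(h @ W2.T)))


def scale_and_stack(Z: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Feature matrix: row j of the output is u_j * z_j."""
    Z = np.asarray(Z, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if Z.shape[:-1] != u.shape:
        raise ShapeError(f"weight shape {u.shape} does not match rows {Z.shape[:-1]}")
    return Z * u[..., None]


def attention_forward(Z: np.ndarray, params: Dict[str, np.ndarray]):
    """Batched squeeze -> excite -> scale.  Returns (Zhat, cache)."""
    s = squeeze(Z)
    pre1 = s @ params["W1"].T
    h = np.maximum(pre1, 0.0)
    pre2 = h @ params["W2"].T
    u = 1.0 / (1.0 + np.exp(-pre2))
    Zhat = Z * u[..., None]
    cache = {"Z": Z, "s": s, "pre1": pre1, "h": h, "u": u}
    return Zhat, cache


def attention_backward(dZhat: np.ndarray, cache: dict,
                       params: Dict[str, np.ndarray]):
    """Gradients through scale -> excite -> squeeze.

    Returns ``(dZ, grads)`` with grads for W1 and W2.  ``dZhat`` is
    (N, J+1, d), matching the forward batch.
    """
    Z, u, h = cache["Z"], cache["u"], cache["h"]
    du = np.einsum("njd,njd->nj", dZhat, Z)
    dZ = dZhat * u[..., None]
    dpre2 = du * u * (1.0 - u)
    gW2 = np.einsum("nj,nh->jh", dpre2, h)
    dh = dpre2 @ params["W2"]
    dpre1 = dh * (cache["pre1"] > 0)
    gW1 = np.einsum("nh,nj->hj", dpre1, cache["s"])
    ds = dpre1 @ params["W1"]
    d_feat = Z.shape[-1]
    dZ += ds[..., None] / d_feat
    return dZ, {"W1": gW1, "W2": gW2}
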