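"""Shallow convolutional EEG feature extractor (AConvNet) in pure numpy.

Layer stack for one ``m x t`` input (a region's channels, or all of them
for the global branch):

  temporal conv (1 x 25, 40 filters, valid, stride 1)  -> 40 x m x (t-24)
  spatial conv  (m x 1, 40 filters over all maps)      -> 40 x (t-24)
  batch normalization (per feature map)                -> 40 x (t-24)
  square -> average pool (1 x 75, stride 15) -> log    -> 40 x P
  flatten -> dense                                     -> d_feat (300)

with ``P = floor((t-99)/15) + 1``.  The squared, pooled, logged band
signal is a log band-power estimate, which is why this family of shallow
nets works on oscillatory EEG.  Everything is float64 with hand-written
backward passes, so analytic gradients can be checked against central
differences to tight tolerances.

A standalone two-layer classification head (dense ``d_feat x K`` with
softmax cross-entropy) turns one extractor into the plain-backbone
baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigError, DataError, ShapeError

__all__ = [
    "BackboneConfig",
    "feature_map_shape",
    "init_backbone_params",
    "backbone_forward",
    "backbone_backward",
    "extract_features",
    "init_head_params",
    "backbone_classify",
    "train_backbone_baseline",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture constants of the extractor (defaults: reference net)."""

    temporal_filters: int = 40
    temporal_kernel: int = 25
    pool_len: int = 75
    pool_stride: int = 15
    d_feat: int = 300
    n_classes: int = 2
    log_epsilon: float = 1e-6
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self):
        if min(self.temporal_filters, self.temporal_kernel, self.pool_len,
               self.pool_stride, self.d_feat, self.n_classes) < 1:
            raise ConfigError("all architecture counts must be positive")
        if self.pool_len <= self.pool_stride:
            raise ConfigError("pool_len must exceed pool_stride")
        if self.log_epsilon <= 0:
            raise ConfigError("log_epsilon must be positive")

    @property
    def min_samples(self) -> int:
        return self.temporal_kernel + self.pool_len - 1

    def conv_len(self, t: int) -> int:
        return t - self.temporal_kernel + 1

    def pooled_len(self, t: int) -> int:
        return (self.conv_len(t) - self.pool_len) // self.pool_stride + 1

    def flatten_len(self, t: int) -> int:
        return self.temporal_filters * self.pooled_len(t)


def feature_map_shape(m: int, t: int, cfg: BackboneConfig = BackboneConfig()) -> List[Tuple[str, tuple]]:
    """Layer-by-layer output shapes for an ``m x t`` input.

    Returns ``[(layer name, shape), ...]`` following the closed forms:
    temporal conv keeps m rows and shortens time to ``t - kernel + 1``;
    the spatial conv collapses the channel axis; pooling yields
    ``floor((conv_len - pool_len)/stride) + 1`` frames.
    """
    if m < 1 or t < 1:
        raise ShapeError(f"need m >= 1 and t >= 1, got ({m}, {t})")
    if t < cfg.min_samples:
        raise ShapeError(
            f"trial too short: t={t} below the minimum of {cfg.min_samples} "
            f"samples required by kernel {cfg.temporal_kernel} + pool {cfg.pool_len}"
        )
    f = cfg.temporal_filters
    ct, p = cfg.conv_len(t), cfg.pooled_len(t)
    return [
        ("input", (m, t)),
        ("temporal_conv", (f, m, ct)),
        ("spatial_conv", (f, ct)),
        ("batchnorm", (f, ct)),
        ("square", (f, ct)),
        ("avgpool", (f, p)),
        ("log", (f, p)),
        ("flatten", (f * p,)),
        ("dense", (cfg.d_feat,)),
    ]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def init_backbone_params(m: int, t: int, cfg: BackboneConfig,
                         rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, identity batch-norm."""
    feature_map_shape(m, t, cfg)  # validates m, t
    f, k = cfg.temporal_filters, cfg.temporal_kernel
    flat = cfg.flatten_len(t)
    return {
        "Wt": _glorot(rng, (f, k), k, f),
        "bt": np.zeros(f),
        "Ws": _glorot(rng, (f, f, m), f * m, f),
        "bs": np.zeros(f),
        "gamma": np.ones(f),
        "beta": np.zeros(f),
        "Wd": _glorot(rng, (cfg.d_feat, flat), flat, cfg.d_feat),
        "bd": np.zeros(cfg.d_feat),
        # batch-norm running statistics (state, not trained parameters)
        "run_mean": np.zeros(f),
        "run_var": np.ones(f),
    }


TRAINABLE = ("Wt", "bt", "Ws", "bs", "gamma", "beta", "Wd", "bd")


def backbone_forward(X: np.ndarray, params: Dict[str, np.ndarray],
                     cfg: BackboneConfig, training: bool = False,
                     update_stats: bool = False):
    """Forward pass on a batch ``X`` of shape (N, m, t).

    Returns ``(z, cache)`` with ``z`` of shape (N, d_feat).  In training
    mode batch statistics normalize; in evaluation mode the stored running
    statistics do.  ``update_stats`` folds the batch statistics into the
    running averages (side effect on ``params``).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ShapeError(f"expected batch of matrices (N, m, t), got ndim={X.ndim}")
    if not np.isfinite(X).all():
        raise DataError("non-finite values in backbone input")
    N, m, t = X.shape
    feature_map_shape(m, t, cfg)
    L, R = cfg.pool_len, cfg.pool_stride
    P = cfg.pooled_len(t)
    ct = cfg.conv_len(t)
    k = cfg.temporal_kernel

    # The temporal and spatial convolutions compose linearly (no activation
    # between them), so they are evaluated as one composite kernel
    # K[g,c,k] = sum_f Ws[g,f,c] Wt[f,k] applied to the im2col windows —
    # exactly equivalent to applying them in sequence, and one big matmul.
    Xw = sliding_window_view(X, k, axis=2)  # (N, m, ct, k) strided view
    Xc = np.ascontiguousarray(Xw.transpose(0, 2, 1, 3)).reshape(N, ct, m * k)
    K = np.einsum("gfc,fk->gck", params["Ws"], params["Wt"])
    beff = params["bs"] + np.einsum("gfc,f->g", params["Ws"], params["bt"])
    B = (Xc @ K.reshape(cfg.temporal_filters, m * k).T)  # (N, ct, g)
    B = B.transpose(0, 2, 1) + beff[None, :, None]  # (N, g, ct)

    if training:
        mu = B.mean(axis=(0, 2))
        var = B.var(axis=(0, 2))
        if update_stats:
            mom = cfg.bn_momentum
            params["run_mean"] *= 1 - mom
            params["run_mean"] += mom * mu
            params["run_var"] *= 1 - mom
            params["run_var"] += mom * var
    else:
        mu, var = params["run_mean"], params["run_var"]
    std = np.sqrt(var + cfg.bn_eps)
    xhat = (B - mu[None, :, None]) / std[None, :, None]
    Bn = params["gamma"][None, :, None] * xhat + params["beta"][None, :, None]

    S = Bn ** 2
    pooled = np.empty((N, cfg.temporal_filters, P))
    for p in range(P):
        pooled[:, :, p] = S[:, :, p * R:p * R + L].mean(axis=2)
    clamped = np.maximum(pooled, cfg.log_epsilon)
    Lg = np.log(clamped)
    flat = Lg.reshape(N, -1)
    z = flat @ params["Wd"].T + params["bd"]

    cache = {
        "Xc": Xc, "xhat": xhat, "std": std, "Bn": Bn,
        "pooled": pooled, "clamped": clamped, "flat": flat,
        "training": training, "shape": (N, m, t),
    }
    return z, cache


def backbone_backward(dz: np.ndarray, cache: dict, params: Dict[str, np.ndarray],
                      cfg: BackboneConfig) -> Dict[str, np.ndarray]:
    """Backward pass: gradients of a scalar loss w.r.t. every parameter.

    ``dz`` is dLoss/dz with z the (N, d_feat) output of the matching
    forward call.  The batch-norm backward accounts for the dependence of
    the batch statistics on every sample when the forward ran in training
    mode.
    """
    N, m, t = cache["shape"]
    L, R = cfg.pool_len, cfg.pool_stride
    P = cfg.pooled_len(t)
    grads: Dict[str, np.ndarray] = {}

    grads["Wd"] = dz.T @ cache["flat"]
    grads["bd"] = dz.sum(axis=0)
    dflat = dz @ params["Wd"]
    dLg = dflat.reshape(N, cfg.temporal_filters, P)

    dpooled = dLg / cache["clamped"]
    dpooled[cache["pooled"] < cfg.log_epsilon] = 0.0

    ct = cfg.conv_len(t)
    dS = np.zeros((N, cfg.temporal_filters, ct))
    for p in range(P):
        dS[:, :, p * R:p * R + L] += dpooled[:, :, p, None] / L

    dBn = 2.0 * cache["Bn"] * dS
    xhat, std = cache["xhat"], cache["std"]
    grads["gamma"] = (dBn * xhat).sum(axis=(0, 2))
    grads["beta"] = dBn.sum(axis=(0, 2))
    dxhat = dBn * params["gamma"][None, :, None]
    if cache["training"]:
        n_eff = N * ct
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dB = (dxhat - sum_dxhat / n_eff - xhat * sum_dxhat_xhat / n_eff) / std[None, :, None]
    else:
        dB = dxhat / std[None, :, None]

    # chain back through the composite conv kernel (see forward)
    k = cfg.temporal_kernel
    f = cfg.temporal_filters
    dBt = dB.transpose(0, 2, 1)  # (N, ct, g)
    dK = np.tensordot(cache["Xc"], dBt, axes=([0, 1], [0, 1])).T  # (g, m*k)
    dK = dK.reshape(f, m, k)
    dbeff = dB.sum(axis=(0, 2))
    grads["bs"] = dbeff
    grads["bt"] = np.einsum("g,gfc->f", dbeff, params["Ws"])
    grads["Wt"] = np.einsum("gck,gfc->fk", dK, params["Ws"])
    grads["Ws"] = np.einsum("gck,fk->gfc", dK, params["Wt"])
    grads["Ws"] += dbeff[:, None, None] * params["bt"][None, :, None]
    return grads


def extract_features(X: np.ndarray, params: Dict[str, np.ndarray],
                     cfg: BackboneConfig = BackboneConfig()) -> np.ndarray:
    """Deep feature vector z (length d_feat) of one ``m x t`` matrix.

    Evaluation-mode convenience wrapper around :func:`backbone_forward`.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ShapeError("extract_features expects a single (m, t) matrix")
    z, _ = backbone_forward(X[None], params, cfg, training=False)
    return z[0]


def init_head_params(cfg: BackboneConfig, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Second dense layer (d_feat -> K) of the standalone baseline."""
    return {
        "Wk": _glorot(rng, (cfg.n_classes, cfg.d_feat), cfg.d_feat, cfg.n_classes),
        "bk": np.zeros(cfg.n_classes),
    }


def backbone_classify(X: np.ndarray, params: Dict[str, np.ndarray],
                      head: Dict[str, np.ndarray],
                      cfg: BackboneConfig = BackboneConfig()) -> np.ndarray:
    """K-vector of class scores of the plain-backbone baseline."""
    z = extract_features(X, params, cfg)
    return head["Wk"] @ z + head["bk"]


def _softmax_xent(scores: np.ndarray, onehot_idx: np.ndarray):
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    probs = expd / expd.sum(axis=1, keepdims=True)
    n = scores.shape[0]
    loss = -np.log(probs[np.arange(n), onehot_idx] + 1e-300).mean()
    dscores = probs.copy()
    dscores[np.arange(n), onehot_idx] -= 1.0
    return loss, dscores / n


def train_backbone_baseline(X: np.ndarray, y: np.ndarray, cfg: BackboneConfig,
                            epochs: int = 50, lr: float = 1e-3,
                            batch_size: int = 40, seed: int = 0):
    """Fit the standalone baseline (extractor + softmax head) with SGD.

    ``X``: (N, m, t) global trial matrices; ``y``: labels in {+1, -1}
    (mapped to classes 1/0).  Returns ``(params, head, history)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y_idx = (np.asarray(y) > 0).astype(int)
    rng = np.random.default_rng(seed)
    N, m, t = X.shape
    params = init_backbone_params(m, t, cfg, rng)
    head = init_head_params(cfg, rng)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, batch_size):
            idx = order[start:start + batch_size]
            z, cache = backbone_forward(X[idx], params, cfg, training=True,
                                        update_stats=True)
            scores = z @ head["Wk"].T + head["bk"]
            loss, dscores = _softmax_xent(scores, y_idx[idx])
            dWk = dscores.T @ z
            dbk = dscores.sum(axis=0)
            dz = dscores @ head["Wk"]
            grads = backbone_backward(dz, cache, params, cfg)
            for name in TRAINABLE:
                params[name] -= lr * grads[name]
            head["Wk"] -= lr * dWk
            head["bk"] -= lr * dbk
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return params, head, history
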