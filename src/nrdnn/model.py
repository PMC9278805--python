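"""End-to-end model: J+1 region extractors -> region attention -> matrix head.

Each brain region (and the global montage) gets its own independently
parameterized convolutional extractor; the attention layer reweights the
resulting J+1 feature vectors; the weighted vectors are stacked into a
(J+1) x d_feat matrix classified by the nuclear-norm-regularized hinge
head.  The whole chain is differentiable (subgradients at the hinge kink
and nuclear term), so one backward pass yields gradients for every
parameter group and plain SGD trains it end to end.

Disabling attention (``attention=False``) freezes u at 1 and drops the
gating parameters: the plain region-stacking ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import attention as att
from . import backbone as bb
from .backbone import BackboneConfig, TRAINABLE
from .exceptions import DataError, ShapeError
from .matrix_head import (
    MatrixClassifier,
    hinge_loss,
    nuclear_norm,
    nuclear_subgradient,
)
from .montage import EEGTrial, RegionMap, partition_trial

__all__ = ["NRDNNModel", "stack_region_tensors"]


def stack_region_tensors(trials: Sequence[EEGTrial], region_map: RegionMap):
    """Partition a list of same-shape trials into batched region tensors.

    Returns ``(parts, y)`` where ``parts`` is a list of J+1 arrays — one
    (N, m_j, t) tensor per region plus the (N, m, t) global tensor — and
    ``y`` the (N,) label vector (entries 0 where a trial is unlabelled).
    """
    if not trials:
        raise DataError("no trials given")
    bundles = [partition_trial(tr, region_map) for tr in trials]
    J = region_map.J
    parts = [
        np.stack([b.parts[j] for b in bundles]) for j in range(J)
    ]
    parts.append(np.stack([b.global_part for b in bundles]))
    y = np.array([0 if tr.label is None else tr.label for tr in trials])
    return parts, y


class NRDNNModel:
    """The full region-attentive matrix-classifying network.

    Parameters
    ----------
    region_map : RegionMap
        Channel-to-region assignment; fixes J and the row counts m_j.
    n_samples : int
        Trial length t in samples (fixes the dense-layer fan-in).
    backbone_cfg : BackboneConfig
        Extractor architecture.
    C, tau : float
        Hinge trade-off and nuclear penalty of the matrix head.
    r : int
        Reduction ratio of the attention bottleneck.
    attention : bool
        False freezes the region weights at 1 (the ablation).
    seed : int
        Seeds the Glorot initialization of every parameter group.
    """

    def __init__(self, region_map: RegionMap, n_samples: int,
                 backbone_cfg: BackboneConfig = BackboneConfig(),
                 C: float = 1.0, tau: float = 1e-2, r: int = 2,
                 attention: bool = True, seed: int = 0):
        self.region_map = region_map
        self.n_samples = int(n_samples)
        self.cfg = backbone_cfg
        self.attention = bool(attention)
        self.r = int(r)
        rng = np.random.default_rng(seed)
        sizes = list(region_map.sizes) + [sum(region_map.sizes)]
        self.extractors = [
            bb.init_backbone_params(m, self.n_samples, backbone_cfg, rng)
            for m in sizes
        ]
        self.n_branches = len(sizes)  # J + 1
        self.att_params = (
            att.init_attention_params(self.n_branches, self.r, rng)
            if self.attention else None
        )
        lim = np.sqrt(6.0 / (self.n_branches + backbone_cfg.d_feat))
        self.clf = MatrixClassifier(
            W=rng.uniform(-lim, lim, (self.n_branches, backbone_cfg.d_feat)),
            b=0.0, C=C, tau=tau,
        )

    # ---------------------------------------------------------------- forward

    def _check_parts(self, parts) -> None:
        if len(parts) != self.n_branches:
            raise ShapeError(
                f"expected {self.n_branches} region tensors, got {len(parts)}"
            )

    def forward(self, parts, training: bool = False, update_stats: bool = False):
        """Scores for a batch of partitioned trials.

        Returns ``(scores, aux)``; ``aux`` carries the feature stack Zhat,
        the attention weights u and the per-branch caches needed by
        :meth:`backward`.
        """
        self._check_parts(parts)
        zs, caches = [], []
        for j in range(self.n_branches):
            z, cache = bb.backbone_forward(
                parts[j], self.extractors[j], self.cfg,
                training=training, update_stats=update_stats,
            )
            zs.append(z)
            caches.append(cache)
        Z = np.stack(zs, axis=1)  # (N, J+1, d_feat)
        if self.attention:
            Zhat, att_cache = att.attention_forward(Z, self.att_params)
            u = att_cache["u"]
        else:
            Zhat, att_cache = Z, None
            u = np.ones(Z.shape[:2])
        scores = np.einsum("njd,jd->n", Zhat, self.clf.W) + self.clf.b
        aux = {"Z": Z, "Zhat": Zhat, "u": u, "scores": scores,
               "caches": caches, "att_cache": att_cache}
        return scores, aux

    def loss(self, parts, y: np.ndarray, training: bool = True,
             update_stats: bool = False):
        """Objective value on a batch: regularizers + C * sum of hinges."""
        scores, aux = self.forward(parts, training=training,
                                   update_stats=update_stats)
        y = np.asarray(y)
        margins = 1.0 - y * scores
        hinges = np.maximum(margins, 0.0)
        W = self.clf.W
        value = (0.5 * float(np.sum(W ** 2)) + self.clf.tau * nuclear_norm(W)
                 + self.clf.C * float(hinges.sum()))
        aux["hinges"] = hinges
        return value, aux

    # --------------------------------------------------------------- backward

    def backward(self, y: np.ndarray, aux) -> dict:
        """Gradients of the batch objective w.r.t. every parameter group.

        Returns ``{"extractors": [per-branch dict...], "attention": dict
        or None, "W": array, "b": float}``.
        """
        y = np.asarray(y)
        active = (aux["hinges"] > 0).astype(np.float64)
        coef = -self.clf.C * y * active  # dLoss/dscore_i
        W = self.clf.W
        gW = W + self.clf.tau * nuclear_subgradient(W)
        gW = gW + np.einsum("n,njd->jd", coef, aux["Zhat"])
        gb = float(coef.sum())
        dZhat = coef[:, None, None] * W[None, :, :]
        if self.attention:
            dZ, g_att = att.attention_backward(dZhat, aux["att_cache"],
                                               self.att_params)
        else:
            dZ, g_att = dZhat, None
        g_extractors = []
        for j in range(self.n_branches):
            grads = bb.backbone_backward(dZ[:, j, :], aux["caches"][j],
                                         self.extractors[j], self.cfg)
            g_extractors.append(grads)
        return {"extractors": g_extractors, "attention": g_att,
                "W": gW, "b": gb}

    def sgd_step(self, grads: dict, lr: float) -> None:
        """One plain SGD update of every trainable parameter group."""
        for params, g in zip(self.extractors, grads["extractors"]):
            for name in TRAINABLE:
                params[name] -= lr * g[name]
        if self.attention and grads["attention"] is not None:
            self.att_params["W1"] -= lr * grads["attention"]["W1"]
            self.att_params["W2"] -= lr * grads["attention"]["W2"]
        self.clf.W = self.clf.W - lr * grads["W"]
        self.clf.b = self.clf.b - lr * grads["b"]

    # ------------------------------------------------------------- evaluation

    def predict_scores(self, parts) -> np.ndarray:
        """Evaluation-mode decision scores for a batch."""
        scores, _ = self.forward(parts, training=False)
        return scores

    def predict_labels(self, parts) -> np.ndarray:
        scores = self.predict_scores(parts)
        return np.where(scores >= 0, 1, -1)

    def attention_weights(self, parts) -> np.ndarray:
        """Per-trial region weights u, shape (N, J+1), in evaluation mode."""
        _, aux = self.forward(parts, training=False)
        return aux["u"]

    # ---------------------------------------------- parameter (de)serialization

    def parameter_arrays(self) -> Dict[str, np.ndarray]:
        """Flat name -> array view of all parameters and BN state."""
        out: Dict[str, np.ndarray] = {}
        for j, params in enumerate(self.extractors):
            for name, arr in params.items():
                out[f"ext{j}.{name}"] = arr
        if self.attention:
            out["att.W1"] = self.att_params["W1"]
            out["att.W2"] = self.att_params["W2"]
        out["clf.W"] = self.clf.W
        out["clf.b"] = np.array([self.clf.b])
        return out

    def load_parameter_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        for j, params in enumerate(self.extractors):
            for name in params:
                key = f"ext{j}.{name}"
                if key not in arrays:
                    raise ShapeError(f"checkpoint missing {key}")
                if arrays[key].shape != params[name].shape:
                    raise ShapeError(f"checkpoint shape mismatch at {key}")
                params[name] = arrays[key].astype(np.float64).copy()
        if self.attention:
            self.att_params["W1"] = arrays["att.W1"].astype(np.float64).copy()
            self.att_params["W2"] = arrays["att.W2"].astype(np.float64).copy()
        self.clf.W = arrays["clf.W"].astype(np.float64).copy()
        self.clf.b = float(np.asarray(arrays["clf.b"]).ravel()[0])
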