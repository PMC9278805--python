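"""Convolutional feature extractor: shapes, features, gradients."""

import numpy as np
import pytest

from nrdnn import BackboneConfig, extract_features, feature_map_shape
from nrdnn.backbone import (
    TRAINABLE,
    backbone_backward,
    backbone_classify,
    backbone_forward,
    init_backbone_params,
    init_head_params,
    train_backbone_baseline,
)
from nrdnn.exceptions import DataError, ShapeError

from conftest import central_difference, relative_error


def shapes_dict(m, t, cfg=BackboneConfig()):
    return dict(feature_map_shape(m, t, cfg))


@pytest.mark.parametrize("m,t,conv,pooled,flat", [
    (32, 512, 488, 28, 1120),
    (2, 128, 104, 2, 80),
    (5, 99, 75, 1, 40),
])
def test_layer_shape_closed_forms(m, t, conv, pooled, flat):
    s = shapes_dict(m, t)
    assert s["temporal_conv"] == (40, m, conv)
    assert s["spatial_conv"] == (40, conv)
    assert s["avgpool"] == (40, pooled)
    assert s["flatten"] == (flat,)
    assert s["dense"] == (300,)


def test_too_short_trial_names_minimum():
    with pytest.raises(ShapeError, match="99"):
        feature_map_shape(5, 98)


def test_shape_propagation_matches_formula_for_random_sizes():
    """Actual forward-pass shapes agree with the closed forms (50 draws)."""
    cfg = BackboneConfig(temporal_filters=3, d_feat=6)
    rng = np.random.default_rng(11)
    for _ in range(50):
        m = int(rng.integers(1, 12))
        t = int(rng.integers(cfg.min_samples, 300))
        params = init_backbone_params(m, t, cfg, rng)
        z, cache = backbone_forward(rng.normal(size=(2, m, t)), params, cfg)
        s = shapes_dict(m, t, cfg)
        assert z.shape == (2, cfg.d_feat)
        assert cache["pooled"].shape[1:] == s["avgpool"]
        assert cache["flat"].shape[1] == s["flatten"][0]


def test_feature_length_is_d_feat_regardless_of_channel_count():
    cfg = BackboneConfig()
    rng = np.random.default_rng(0)
    for m in (2, 9, 32):
        params = init_backbone_params(m, 256, cfg, rng)
        z = extract_features(rng.normal(size=(m, 256)), params, cfg)
        assert z.shape == (300,)
        assert np.isfinite(z).all()


def test_zero_input_is_clamped_to_finite_features():
    cfg = BackboneConfig(temporal_filters=4, d_feat=8)
    rng = np.random.default_rng(1)
    params = init_backbone_params(3, 120, cfg, rng)
    z = extract_features(np.zeros((3, 120)), params, cfg)
    assert np.isfinite(z).all()


def test_inference_mode_is_deterministic():
    cfg = BackboneConfig(temporal_filters=4, d_feat=8)
    rng = np.random.default_rng(2)
    params = init_backbone_params(3, 120, cfg, rng)
    X = rng.normal(size=(3, 120))
    np.testing.assert_array_equal(extract_features(X, params, cfg),
                                  extract_features(X, params, cfg))


def test_nonfinite_input_rejected():
    cfg = BackboneConfig(temporal_filters=4, d_feat=8)
    params = init_backbone_params(2, 120, cfg, np.random.default_rng(0))
    X = np.zeros((1, 2, 120))
    X[0, 0, 0] = np.nan
    with pytest.raises(DataError):
        backbone_forward(X, params, cfg)


def test_extractors_have_independent_parameters():
    """Mutating one extractor's weights leaves another's output unchanged."""
    cfg = BackboneConfig(temporal_filters=4, d_feat=8)
    rng = np.random.default_rng(3)
    p1 = init_backbone_params(3, 120, cfg, rng)
    p2 = init_backbone_params(3, 120, cfg, rng)
    X = rng.normal(size=(3, 120))
    before = extract_features(X, p2, cfg)
    p1["Wd"] += 10.0
    np.testing.assert_array_equal(extract_features(X, p2, cfg), before)


def test_backbone_gradients_match_central_differences():
    """Analytic backprop vs numerics through the whole extractor stack."""
    cfg = BackboneConfig(temporal_filters=2, d_feat=5)
    rng = np.random.default_rng(4)
    m, t, N = 3, 120, 3
    X = rng.normal(size=(N, m, t))
    params = init_backbone_params(m, t, cfg, rng)
    v = rng.normal(size=(N, cfg.d_feat))  # random linear functional of z

    def value():
        z, _ = backbone_forward(X, params, cfg, training=True)
        return float(np.sum(v * z))

    z, cache = backbone_forward(X, params, cfg, training=True)
    grads = backbone_backward(v, cache, params, cfg)
    for name in TRAINABLE:
        num = central_difference(value, params[name])
        assert relative_error(grads[name], num) < 1e-4, name


def test_dense_head_cross_entropy_gradient():
    """Baseline head gradient (dWk, dbk) matches numerics on a tiny case."""
    from nrdnn.backbone import _softmax_xent

    cfg = BackboneConfig(temporal_filters=2, d_feat=5)
    rng = np.random.default_rng(5)
    params = init_backbone_params(3, 120, cfg, rng)
    head = init_head_params(cfg, rng)
    X = rng.normal(size=(4, 3, 120))
    y_idx = np.array([0, 1, 0, 1])

    def value():
        z, _ = backbone_forward(X, params, cfg, training=True)
        scores = z @ head["Wk"].T + head["bk"]
        loss, _ = _softmax_xent(scores, y_idx)
        return loss

    z, cache = backbone_forward(X, params, cfg, training=True)
    scores = z @ head["Wk"].T + head["bk"]
    _, dscores = _softmax_xent(scores, y_idx)
    dWk = dscores.T @ z
    dz = dscores @ head["Wk"]
    grads = backbone_backward(dz, cache, params, cfg)
    assert relative_error(dWk, central_difference(value, head["Wk"])) < 1e-4
    assert relative_error(grads["Wd"], central_difference(value, params["Wd"])) < 1e-4


def test_constant_head_gives_constant_scores():
    cfg = BackboneConfig(temporal_filters=4, d_feat=8)
    rng = np.random.default_rng(6)
    params = init_backbone_params(3, 120, cfg, rng)
    head = {"Wk": np.zeros((2, cfg.d_feat)), "bk": np.array([1.5, -0.5])}
    for _ in range(3):
        scores = backbone_classify(rng.normal(size=(3, 120)), params, head, cfg)
        np.testing.assert_allclose(scores, [1.5, -0.5])


def test_baseline_fits_separable_global_signal():
    """The plain backbone + softmax head learns a separable toy dataset."""
    rng = np.random.default_rng(8)
    N, m, t = 24, 4, 128
    y = np.array([1, -1] * (N // 2))
    time = np.arange(t) / 128.0
    X = rng.normal(0, 1.0, size=(N, m, t))
    X[y == 1] += 3.0 * np.sin(2 * np.pi * 10.0 * time)
    cfg = BackboneConfig(temporal_filters=8, d_feat=16)
    params, head, history = train_backbone_baseline(
        X, y, cfg, epochs=30, lr=1e-3, batch_size=12, seed=0)
    preds = []
    for i in range(N):
        scores = backbone_classify(X[i], params, head, cfg)
        preds.append(1 if scores[1] > scores[0] else -1)
    assert np.mean(np.array(preds) == y) >= 0.95
    assert history[-1] < history[0]
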