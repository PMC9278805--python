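"""Training loop, schedule, grid search and leave-one-subject-out."""

import numpy as np
import pytest

from nrdnn import (
    BackboneConfig,
    SynthConfig,
    TrainConfig,
    generate_dataset,
    grid_search,
    loso_evaluate,
    lr_schedule,
    stack_region_tensors,
    train_nrdnn,
)
from nrdnn.exceptions import ConfigError, DegenerateDataError

FAST = dict(backbone=BackboneConfig(temporal_filters=8, d_feat=16), epochs=8)


def test_lr_schedule_endpoints_and_flat_case():
    cfg = TrainConfig()
    assert lr_schedule(0.0, cfg) == pytest.approx(1e-3)
    assert lr_schedule(1.0, cfg) == pytest.approx(1e-3 / 11 ** 0.75)
    flat = TrainConfig(alpha=0.0)
    assert lr_schedule(0.37, flat) == pytest.approx(flat.eta0)
    with pytest.raises(ConfigError):
        lr_schedule(1.5, cfg)


def test_lr_schedule_monotone_decreasing():
    cfg = TrainConfig()
    ps = np.linspace(0, 1, 21)
    lrs = [lr_schedule(p, cfg) for p in ps]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))


def test_training_is_deterministic(deap_map):
    cfg = SynthConfig(n_subjects=2, trials_per_subject=6, duration=1.0, seed=2)
    trials = generate_dataset(cfg)
    tcfg = TrainConfig(seed=5, **FAST)
    m1, h1 = train_nrdnn(trials, deap_map, tcfg)
    m2, h2 = train_nrdnn(trials, deap_map, tcfg)
    assert h1["loss"] == h2["loss"]
    parts, y = stack_region_tensors(trials, deap_map)
    np.testing.assert_array_equal(m1.predict_scores(parts),
                                  m2.predict_scores(parts))


def test_training_rejects_degenerate_sets(deap_map):
    cfg = SynthConfig(n_subjects=1, trials_per_subject=4, duration=1.0, seed=0)
    trials = generate_dataset(cfg)
    single_class = [t for t in trials if t.label == 1]
    tcfg = TrainConfig(**FAST)
    with pytest.raises(DegenerateDataError):
        train_nrdnn(single_class, deap_map, tcfg)
    with pytest.raises(DegenerateDataError):
        train_nrdnn(trials[:1], deap_map, tcfg)


def test_grid_search_single_point_short_circuits(deap_map):
    cfg = SynthConfig(n_subjects=1, trials_per_subject=4, duration=1.0, seed=0)
    trials = generate_dataset(cfg)
    tcfg = TrainConfig(C_grid=(2.0,), tau_grid=(0.3,), **FAST)
    assert grid_search(trials, deap_map, tcfg) == (2.0, 0.3)


def test_grid_search_prefers_better_candidate(deap_map):
    """An absurdly small C cannot learn; the sane candidate must win."""
    cfg = SynthConfig(n_subjects=1, trials_per_subject=20, duration=1.0, seed=3)
    trials = generate_dataset(cfg)
    tcfg = TrainConfig(C_grid=(1e-9, 1.0), tau_grid=(1e-2,), cv_folds=2,
                       seed=1, **FAST)
    C, tau = grid_search(trials, deap_map, tcfg)
    assert (C, tau) == (1.0, 1e-2)


def test_grid_candidate_count_matches_grids():
    cfg = TrainConfig()
    assert len(cfg.C_grid) * len(cfg.tau_grid) == 50


def test_loso_bookkeeping_and_no_leakage(deap_map):
    """Every trial tested exactly once; test subject absent from training."""
    cfg = SynthConfig(n_subjects=2, trials_per_subject=4, duration=1.0, seed=4)
    trials = generate_dataset(cfg)
    tcfg = TrainConfig(C_grid=(1.0,), tau_grid=(1e-2,), **FAST)
    result = loso_evaluate(trials, deap_map, tcfg)
    assert [r.subject for r in result.reports] == ["S01", "S02"]
    assert all(r.n_test == 4 for r in result.reports)
    assert sum(r.n_test for r in result.reports) == len(trials)
    for r in result.reports:
        assert r.chosen_C == 1.0 and r.chosen_tau == 1e-2
        assert r.mean_u is not None and r.mean_u.shape == (6,)


def test_loso_requires_multiple_subjects(deap_map):
    cfg = SynthConfig(n_subjects=1, trials_per_subject=4, duration=1.0, seed=0)
    trials = generate_dataset(cfg)
    tcfg = TrainConfig(C_grid=(1.0,), tau_grid=(1e-2,), **FAST)
    with pytest.raises(DegenerateDataError):
        loso_evaluate(trials, deap_map, tcfg)


def test_ablation_flag_freezes_attention(deap_map):
    cfg = SynthConfig(n_subjects=2, trials_per_subject=4, duration=1.0, seed=6)
    trials = generate_dataset(cfg)
    tcfg = TrainConfig(attention_enabled=False, **FAST)
    model, _ = train_nrdnn(trials, deap_map, tcfg)
    parts, _ = stack_region_tensors(trials, deap_map)
    np.testing.assert_allclose(model.attention_weights(parts), 1.0)
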