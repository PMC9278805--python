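import numpy as np
import pytest

from nrdnn import (
    BackboneConfig,
    EEGTrial,
    RegionMap,
    SynthConfig,
    deap32_region_map,
    generate_dataset,
)


@pytest.fixture(scope="session")
def deap_map():
    return deap32_region_map()


@pytest.fixture(scope="session")
def toy_map():
    return RegionMap((("A", ("c1", "c2")), ("B", ("c3", "c4"))))


@pytest.fixture(scope="session")
def tiny_backbone_cfg():
    """Few filters, short features: fast exact gradient checks."""
    return BackboneConfig(temporal_filters=4, d_feat=8)


@pytest.fixture(scope="session")
def toy_trials(toy_map):
    """Four labelled 4-channel trials of 120 samples on the toy montage."""
    rng = np.random.default_rng(7)
    return [
        EEGTrial(rng.normal(size=(4, 120)), 128.0, ("c1", "c2", "c3", "c4"),
                 subject=f"S{1 + i % 2:02d}", label=1 if i % 2 == 0 else -1)
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def small_synth_dataset(deap_map):
    """2 subjects x 10 trials, 1 s at 128 Hz, strongly separable."""
    cfg = SynthConfig(n_subjects=2, trials_per_subject=10, duration=1.0, seed=5)
    return cfg, generate_dataset(cfg)


def relative_error(analytic: np.ndarray, numeric: np.ndarray,
                   floor: float = 1e-2) -> float:
    """Max elementwise |a-n| / max(|a|+|n|, floor).

    The floor compares near-zero pairs (for instance conv-bias gradients,
    which batch norm makes exactly zero) on an absolute scale instead of
    amplifying roundoff.
    """
    analytic = np.asarray(analytic, dtype=np.float64)
    numeric = np.asarray(numeric, dtype=np.float64)
    denom = np.maximum(np.abs(analytic) + np.abs(numeric), floor)
    return float(np.max(np.abs(analytic - numeric) / denom))


def central_difference(fn, arr, eps=1e-6):
    """Central-difference gradient of scalar fn w.r.t. every entry of arr."""
    grad = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = fn()
        arr[i] = orig - eps
        fm = fn()
        arr[i] = orig
        grad[i] = (fp - fm) / (2 * eps)
    return grad
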