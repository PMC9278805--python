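"""Trial preprocessing: resampling, band-pass filtering, label binarization.

The reference pipeline downsamples raw recordings to 128 Hz, band-passes
to 4-45 Hz and binarizes the 1-9 valence rating at 5 (ratings strictly
above the threshold are the positive class; ties go negative).

Resampling uses polyphase anti-aliased resampling; the band-pass is a
4th-order Butterworth applied forward-backward, hence zero-phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .exceptions import ConfigError, DataError
from .montage import EEGTrial

__all__ = [
    "PreprocessConfig",
    "resample_trial",
    "bandpass_trial",
    "binarize_valence",
    "preprocess_trial",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters (defaults follow the reference pipeline)."""

    target_srate: float = 128.0
    band_lo: float = 4.0
    band_hi: float = 45.0
    valence_threshold: float = 5.0

    def __post_init__(self):
        if not (0 < self.band_lo < self.band_hi < self.target_srate / 2):
            raise ConfigError(
                f"need 0 < band_lo < band_hi < target_srate/2, got "
                f"({self.band_lo}, {self.band_hi}) at {self.target_srate} Hz"
            )
        if not (1 < self.valence_threshold < 9):
            raise ConfigError(
                f"valence threshold must lie in (1, 9), got {self.valence_threshold}"
            )


def resample_trial(trial: EEGTrial, target_srate: float) -> EEGTrial:
    """Resample a trial down to ``target_srate`` Hz (polyphase, anti-aliased).

    Upsampling is refused: the pipeline only ever reduces the rate, and
    silently inventing samples would mask configuration mistakes.
    """
    if target_srate > trial.srate:
        raise ConfigError(
            f"upsampling not supported: target {target_srate} Hz above "
            f"original {trial.srate} Hz"
        )
    if target_srate == trial.srate:
        return trial
    ratio = Fraction(target_srate / trial.srate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    # linear-extension padding avoids edge transients on non-zero baselines
    data = signal.resample_poly(trial.data, up, down, axis=1, padtype="line")
    return trial.with_data(data, srate=target_srate)


def bandpass_trial(trial: EEGTrial, lo: float, hi: float, order: int = 4) -> EEGTrial:
    """Zero-phase Butterworth band-pass, applied along time.

    Forward-backward filtering doubles the effective order and cancels the
    phase response, so band-limited components keep their timing.
    """
    if not (0 < lo < hi < trial.srate / 2):
        raise ConfigError(
            f"band edges ({lo}, {hi}) invalid for srate {trial.srate} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trial.srate, output="sos")
    data = signal.sosfiltfilt(sos, trial.data, axis=1)
    return trial.with_data(data)


def binarize_valence(rating: float, threshold: float = 5.0) -> int:
    """Map a 1-9 valence rating to +1 (above threshold) or -1 (at/below).

    A rating exactly at the threshold is assigned to the negative class.
    """
    if not (1 <= rating <= 9):
        raise DataError(f"valence rating must lie in [1, 9], got {rating}")
    return 1 if rating > threshold else -1


def preprocess_trial(trial: EEGTrial, cfg: PreprocessConfig) -> EEGTrial:
    """Resample, band-pass and (if a rating is present) binarize one trial."""
    out = trial
    if trial.srate != cfg.target_srate:
        out = resample_trial(out, cfg.target_srate)
    out = bandpass_trial(out, cfg.band_lo, cfg.band_hi)
    if out.rating is not None and out.label is None:
        from dataclasses import replace

        out = replace(out, label=binarize_valence(out.rating, cfg.valence_threshold))
    return out
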