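"""EMG preprocessing: band-pass filtering, rectification, envelope smoothing.

The chain is the standard surface-EMG conditioning sequence: a 4th-order
Butterworth band-pass (20-450 Hz) removes motion artifacts and powerline
interference, full-wave rectification folds the signal to its magnitude, and
a 200 ms centered moving average yields the activation envelope.

The filter is realized as second-order sections for numerical stability.
``causal`` mode (default) is the single-pass form suitable for an online
controller; ``zero_phase`` applies forward-backward filtering, which removes
phase lag at the cost of doubling the effective order — offline use only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DataError, SamplingError

__all__ = ["FilterMode", "FilterSpec", "SmootherSpec", "bandpass", "rectify", "smooth"]


class FilterMode(str, Enum):
    CAUSAL = "causal"
    ZERO_PHASE = "zero_phase"


@dataclass
class FilterSpec:
    low_cut_hz: float = 20.0
    high_cut_hz: float = 450.0
    order: int = 4
    mode: FilterMode = FilterMode.CAUSAL

    def validate(self, fs: float | None = None) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ConfigurationError(
                f"need 0 < low_cut_hz < high_cut_hz, got "
                f"({self.low_cut_hz}, {self.high_cut_hz})"
            )
        if self.order < 1:
            raise ConfigurationError(f"order must be >= 1, got {self.order}")
        if fs is not None and not self.high_cut_hz < fs / 2:
            raise SamplingError(
                f"high_cut_hz ({self.high_cut_hz}) must be below the Nyquist "
                f"frequency ({fs / 2})"
            )


@dataclass
class SmootherSpec:
    window_ms: float = 200.0

    def validate(self) -> None:
        if self.window_ms <= 0:
            raise ConfigurationError(f"window_ms must be > 0, got {self.window_ms}")


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-section coefficients of the specified Butterworth band-pass."""
    spec.validate(fs)
    return sps.butter(
        spec.order,
        [spec.low_cut_hz, spec.high_cut_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth band-pass a signal; same length out.

    ``zero_phase`` mode uses forward-backward filtering (no phase lag,
    effective order doubled).
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, float)
    if fs <= 2 * spec.high_cut_hz:
        raise SamplingError(
            f"sampling rate {fs} Hz cannot represent the {spec.high_cut_hz} Hz band edge"
        )
    if len(x) <= 3 * spec.order:
        raise DataError(f"signal too short ({len(x)} samples) for order {spec.order}")
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite samples")
    sos = design_sos(spec, fs)
    if spec.mode == FilterMode.ZERO_PHASE:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite samples")
    return np.abs(x)


def smooth(x: np.ndarray, fs: float, spec: SmootherSpec | None = None) -> np.ndarray:
    """Centered moving average with window truncation at the boundaries.

    Truncation (rather than zero padding) avoids biasing the session-start
    calibration statistics low. Output has the input's length.
    """
    spec = spec or SmootherSpec()
    spec.validate()
    x = np.asarray(x, float)
    w = max(int(round(spec.window_ms * fs / 1000.0)), 1)
    n = len(x)
    if w > n:
        raise DataError(f"smoothing window ({w} samples) longer than signal ({n})")
    half_left = (w - 1) // 2
    half_right = w // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.clip(idx - half_left, 0, n)
    hi = np.clip(idx + half_right + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
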