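"""Windowed EMG feature extraction and dual-criterion fatigue labeling.

Features are computed on overlapping 200 ms windows advanced in 100 ms steps.
The five per-window features are the classics of surface-EMG fatigue work:

- RMS (mV): signal energy, ``sqrt(mean(x^2))``
- MAV (mV): contraction level, ``mean(|x|)``
- ZC (count): zero crossings where both neighbors exceed a deadband,
  a cheap frequency correlate
- MF (Hz): mean (power-weighted centroid) frequency of the window
  periodogram, DC bin excluded — the primary fatigue indicator
- MP (mV^2): mean power, ``mean(x^2)`` (so ``mp == rms**2`` identically)

Ground truth is a dual-criterion rule: a window is *Fatigue* only when the
active torque has declined strictly more than ``torque_decline_frac``
(default 20%) **and** the mean frequency has declined at least
``mf_decline_frac`` (default 10%), both relative to session baselines taken
as the mean over the first ``baseline_window_count`` active windows.
Windows failing either criterion are *Non-Fatigue*.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, DataError, LabelingError

__all__ = [
    "WindowSpec",
    "FeatureWindow",
    "LabelingConfig",
    "FatigueLabel",
    "FATIGUE",
    "NON_FATIGUE",
    "FEATURE_NAMES",
    "window_stream",
    "extract_features",
    "extract_feature_table",
    "window_means",
    "label_windows",
    "feature_matrix",
    "features_to_frame",
    "write_feature_table",
    "read_feature_table",
]

FATIGUE = "Fatigue"
NON_FATIGUE = "NonFatigue"
FEATURE_NAMES = ("rms", "mav", "zc", "mf", "mp")


@dataclass
class WindowSpec:
    window_ms: float = 200.0
    step_ms: float = 100.0

    def validate(self) -> None:
        if not 0 < self.step_ms <= self.window_ms:
            raise ConfigurationError(
                f"need 0 < step_ms <= window_ms, got ({self.step_ms}, {self.window_ms})"
            )

    def lengths(self, fs: float) -> tuple[int, int]:
        self.validate()
        w = int(round(self.window_ms * fs / 1000.0))
        s = int(round(self.step_ms * fs / 1000.0))
        return max(w, 1), max(s, 1)


@dataclass
class FeatureWindow:
    """The five features of one analysis window, with half-open time bounds."""

    t_start_s: float
    t_end_s: float
    rms: float
    mav: float
    zc: int
    mf: float
    mp: float
    mf_degenerate: bool = False


@dataclass
class LabelingConfig:
    torque_decline_frac: float = 0.20
    mf_decline_frac: float = 0.10
    baseline_window_count: int = 10

    def validate(self) -> None:
        for name in ("torque_decline_frac", "mf_decline_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.baseline_window_count < 1:
            raise ConfigurationError("baseline_window_count must be >= 1")


@dataclass
class FatigueLabel:
    label: str
    torque_decline_observed: float
    mf_decline_observed: float


def window_stream(
    x: np.ndarray, fs: float, spec: WindowSpec | None = None
) -> Iterator[tuple[float, float, np.ndarray]]:
    """Yield ``(t_start_s, t_end_s, samples)`` for overlapping windows.

    Windows advance by ``step_ms``; a final partial window is dropped.
    Times are seconds from the start of ``x``; bounds half-open.
    """
    spec = spec or WindowSpec()
    x = np.asarray(x, float)
    w, s = spec.lengths(fs)
    if len(x) < w:
        raise DataError(f"signal ({len(x)} samples) shorter than one window ({w})")
    n_win = (len(x) - w) // s + 1
    for i in range(n_win):
        start = i * s
        yield start / fs, (start + w) / fs, x[start : start + w]


def extract_features(
    samples: np.ndarray,
    fs: float,
    zc_deadband_mv: float = 0.0,
    t_start_s: float = 0.0,
    t_end_s: float | None = None,
) -> FeatureWindow:
    """Compute the five features of one window.

    A window with no spectral power off DC (e.g. all zeros) reports ``mf = 0``
    with ``mf_degenerate`` set.
    """
    x = np.asarray(samples, float)
    if x.size == 0:
        raise DataError("empty window")
    if not np.all(np.isfinite(x)):
        raise DataError("window contains non-finite samples")
    if t_end_s is None:
        t_end_s = t_start_s + len(x) / fs

    mp = float(np.mean(x**2))
    rms = float(np.sqrt(mp))
    mav = float(np.mean(np.abs(x)))

    a, b = x[:-1], x[1:]
    zc = int(
        np.count_nonzero(
            (a * b < 0)
            & (np.abs(a) > zc_deadband_mv)
            & (np.abs(b) > zc_deadband_mv)
        )
    )

    freqs, pxx = sps.periodogram(x, fs=fs)
    power = pxx[1:]  # DC excluded
    total = float(power.sum())
    if total <= 0:
        mf, degenerate = 0.0, True
    else:
        mf, degenerate = float(freqs[1:] @ power / total), False

    return FeatureWindow(
        t_start_s=t_start_s,
        t_end_s=t_end_s,
        rms=rms,
        mav=mav,
        zc=zc,
        mf=mf,
        mp=mp,
        mf_degenerate=degenerate,
    )


def extract_feature_table(
    bandpassed: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    spec: WindowSpec | None = None,
    zc_deadband_mv: float = 0.0,
    t_offset_s: float = 0.0,
    paper_strict: bool = False,
) -> list[FeatureWindow]:
    """Window both conditioned signals and merge per-window features.

    Default mode takes the amplitude features (RMS, MAV) from the rectified/
    smoothed envelope and the frequency-bearing features (ZC, MF, MP) from
    the band-passed signal, preserving spectral fidelity. ``paper_strict``
    computes all five on the envelope — the strict post-rectification
    replication path, where ZC degenerates to 0 because the envelope never
    changes sign.
    """
    spec = spec or WindowSpec()
    if len(bandpassed) != len(envelope):
        raise DataError("bandpassed and envelope signals must have equal length")
    rows: list[FeatureWindow] = []
    env_windows = window_stream(envelope, fs, spec)
    for (t0, t1, bp_win), (_, _, env_win) in zip(window_stream(bandpassed, fs, spec), env_windows):
        src_spectral = env_win if paper_strict else bp_win
        fw_spec = extract_features(src_spectral, fs, zc_deadband_mv, t0, t1)
        fw_env = extract_features(env_win, fs, zc_deadband_mv, t0, t1)
        rows.append(
            FeatureWindow(
                t_start_s=t0 + t_offset_s,
                t_end_s=t1 + t_offset_s,
                rms=fw_env.rms,
                mav=fw_env.mav,
                zc=fw_spec.zc,
                mf=fw_spec.mf,
                mp=fw_spec.mp,
                mf_degenerate=fw_spec.mf_degenerate,
            )
        )
    return rows


def window_means(x: np.ndarray, fs: float, spec: WindowSpec | None = None) -> np.ndarray:
    """Per-window means of a synchronized series (e.g. torque), same tiling."""
    return np.array([w.mean() for _, _, w in window_stream(x, fs, spec)])


def label_windows(
    features: Sequence[FeatureWindow],
    window_torque: np.ndarray,
    cfg: LabelingConfig | None = None,
) -> list[FatigueLabel]:
    """Apply the dual-criterion fatigue rule to aligned feature windows.

    Baselines are the mean active torque and mean MF over the first
    ``baseline_window_count`` windows. A window is Fatigue iff its torque
    decline is strictly greater than ``torque_decline_frac`` AND its MF
    decline is at least ``mf_decline_frac``.
    """
    cfg = cfg or LabelingConfig()
    cfg.validate()
    window_torque = np.asarray(window_torque, float)
    if len(window_torque) != len(features):
        raise DataError(
            f"torque windows ({len(window_torque)}) not aligned to feature "
            f"windows ({len(features)})"
        )
    b = cfg.baseline_window_count
    if len(features) < b:
        raise DataError(
            f"need at least baseline_window_count={b} windows, got {len(features)}"
        )
    baseline_torque = float(window_torque[:b].mean())
    if baseline_torque <= 0:
        raise LabelingError(
            "baseline active torque is not positive — active-torque calibration missing"
        )
    baseline_mf = float(np.mean([fw.mf for fw in features[:b]]))
    if baseline_mf <= 0:
        raise LabelingError("baseline mean frequency is not positive")

    labels = []
    for fw, tq in zip(features, window_torque):
        td = (baseline_torque - tq) / baseline_torque
        md = (baseline_mf - fw.mf) / baseline_mf
        fatigued = td > cfg.torque_decline_frac and md >= cfg.mf_decline_frac
        labels.append(
            FatigueLabel(
                label=FATIGUE if fatigued else NON_FATIGUE,
                torque_decline_observed=float(td),
                mf_decline_observed=float(md),
            )
        )
    return labels


# ---------------------------------------------------------------------------
# Tabular views and CSV I/O
# ---------------------------------------------------------------------------

def feature_matrix(features: Sequence[FeatureWindow]) -> np.ndarray:
    """(n_windows, 5) array in FEATURE_NAMES order."""
    return np.array([[fw.rms, fw.mav, fw.zc, fw.mf, fw.mp] for fw in features], float)


def features_to_frame(
    features: Sequence[FeatureWindow], labels: Sequence[FatigueLabel] | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "t_start_s": [f.t_start_s for f in features],
            "t_end_s": [f.t_end_s for f in features],
            "rms": [f.rms for f in features],
            "mav": [f.mav for f in features],
            "zc": [f.zc for f in features],
            "mf": [f.mf for f in features],
            "mp": [f.mp for f in features],
        }
    )
    if labels is not None:
        if len(labels) != len(features):
            raise DataError("labels not aligned to features")
        df["label"] = [l.label for l in labels]
    return df


def write_feature_table(
    features: Sequence[FeatureWindow],
    path: str | pathlib.Path,
    labels: Sequence[FatigueLabel] | None = None,
) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features_to_frame(features, labels).to_csv(path, index=False)
    return path


def read_feature_table(path: str | pathlib.Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("t_start_s", "t_end_s", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise DataError(f"feature CSV missing columns {missing}")
    return df
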