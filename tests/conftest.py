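"""Shared fixtures: synthetic sessions pushed through the preprocessing chain."""

from __future__ import annotations

import numpy as np
import pytest

import fatigueloop as fl
from fatigueloop import features as ft
from fatigueloop import sigproc as sp


def build_feature_dataset(synth_cfg: fl.SynthConfig, n_windows: int | None = None):
    """Generate a session and run it through preprocessing, features and labels."""
    session = fl.generate_session(synth_cfg)
    fs = session.sample_rate_hz
    bp = sp.bandpass(session.emg, fs)
    env = sp.smooth(sp.rectify(bp), fs)
    i0 = session.calib_end_index
    deadband = 3.0 * float(np.sqrt(np.mean(bp[:i0] ** 2))) if i0 > 0 else 0.0
    windows = ft.extract_feature_table(
        bp[i0:], env[i0:], fs, zc_deadband_mv=deadband, t_offset_s=i0 / fs
    )
    window_torque = ft.window_means(session.torque[i0:], fs)
    if n_windows is not None:
        windows, window_torque = windows[:n_windows], window_torque[:n_windows]
    labels = ft.label_windows(windows, window_torque)
    return {
        "session": session,
        "windows": windows,
        "window_torque": window_torque,
        "labels": labels,
        "X": ft.feature_matrix(windows),
        "y": np.array([l.label for l in labels]),
    }


@pytest.fixture(scope="session")
def surrogate_dataset():
    """600 fatiguing windows (MF 90->70 Hz, torque -30%, seed 7): the pooled
    synthetic classifier benchmark."""
    cfg = fl.SynthConfig(duration_s=65.2, calib_duration_s=5.0, seed=7)
    return build_feature_dataset(cfg, n_windows=600)


@pytest.fixture(scope="session")
def strong_fatigue_config():
    """A deeply fatiguing session: MF 90->60 Hz, RMS -30%, torque -50%."""
    return fl.SynthConfig(
        duration_s=65.2,
        calib_duration_s=5.0,
        mf_end_hz=60.0,
        rms_end_mv=0.7,
        torque_end_nm=0.5,
    )
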