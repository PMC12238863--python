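"""Synthetic fatiguing-EMG and joint-torque session generator.

Surface EMG recorded from a fatiguing muscle shows two robust trends: the
power spectrum compresses toward lower frequencies (the mean frequency, MF,
drifts down) and the voluntary torque the joint can produce declines. This
module synthesizes single-channel sessions with exactly that structure so
the whole downstream pipeline (filtering, feature extraction, labeling,
classification, control) can be exercised without any recorded data.

Signal model
------------
The active-segment EMG is amplitude-modulated, band-limited Gaussian noise.
It is built by overlap-adding Hann-windowed bursts of white noise that are
shaped in the frequency domain by a Gaussian band whose center tracks a
linearly drifting target centroid (``mf_start_hz`` → ``mf_end_hz``). Each
burst is normalized to unit variance and the overlap-add window-power sum is
divided out, so the result is unit-RMS everywhere before the linear RMS
envelope (``rms_start_mv`` → ``rms_end_mv``) is applied. A Gaussian band
centered at ``f_c`` has spectral centroid ``f_c``, which makes the target MF
directly verifiable from a periodogram of the output.

Each session starts with a relaxation (calibration) segment of near-zero
activity, emulating the baseline recording used to calibrate the classifier
at the start of a therapy session.

Torque model
------------
Torque is stored on the EMG timebase and follows a linear fatigue schedule
``torque_start_nm`` → ``torque_end_nm`` over the active segment (near zero
during relaxation). Because voluntary joint torque is driven by the same
motor activation the EMG envelope reflects, the realized torque is the
schedule modulated by the normalized slow activation envelope (a
``torque_coupling_ms`` moving average of the rectified EMG divided by its
expected drift): window-to-window effort fluctuations appear coherently in
both signals, as they do physiologically. Setting ``torque_coupling_ms`` to
0 gives an idealized, uncoupled linear torque trace.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import signal as sps

from .errors import ConfigurationError, DataError

__all__ = [
    "SynthConfig",
    "SessionData",
    "generate_session",
    "inject_artifacts",
    "write_session",
    "read_session",
]

#: relaxation-segment RMS as a fraction of the initial active RMS
_CALIB_RMS_FRAC = 0.05
#: relative 1-sigma measurement noise on the torque trace
_TORQUE_NOISE_FRAC = 0.005
#: overlap-add burst length in seconds (50% hop)
_BURST_S = 0.512


@dataclass
class SynthConfig:
    """Parameters of one synthetic therapy session.

    Defaults describe a ~1 minute active bout preceded by a 5 s relaxation
    segment, with the spectral centroid drifting 90 → 70 Hz, a mild RMS
    decline (1.0 → 0.8 mV) and a 30% active-torque decline — a strongly
    fatiguing trial. Artifact amplitudes default to zero; contamination is
    added explicitly with :func:`inject_artifacts`.
    """

    duration_s: float = 65.2
    sample_rate_hz: float = 1000.0
    seed: int = 0
    mf_start_hz: float = 90.0
    mf_end_hz: float = 70.0
    rms_start_mv: float = 1.0
    rms_end_mv: float = 0.8
    torque_start_nm: float = 1.0
    torque_end_nm: float = 0.7
    powerline_hz: float = 50.0
    powerline_amp_mv: float = 0.0
    motion_artifact_amp_mv: float = 0.0
    calib_duration_s: float = 5.0
    #: 1-sigma half-width of the Gaussian spectral band around the target MF
    spectral_sigma_hz: float = 15.0
    #: moving-average span of the activation envelope that modulates torque,
    #: matching the 200 ms envelope scale used throughout the method;
    #: 0 disables EMG-torque coupling (idealized linear torque)
    torque_coupling_ms: float = 200.0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ConfigurationError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.sample_rate_hz > 2 * self.mf_start_hz:
            raise ConfigurationError(
                f"sample_rate_hz ({self.sample_rate_hz}) must exceed "
                f"2 x mf_start_hz ({2 * self.mf_start_hz})"
            )
        if self.mf_end_hz > self.mf_start_hz:
            raise ConfigurationError(
                f"mf_end_hz ({self.mf_end_hz}) must be <= mf_start_hz "
                f"({self.mf_start_hz}): fatigue compresses the spectrum downward"
            )
        if self.mf_end_hz <= 0:
            raise ConfigurationError(f"mf_end_hz must be > 0, got {self.mf_end_hz}")
        if self.rms_start_mv <= 0 or self.rms_end_mv <= 0:
            raise ConfigurationError("rms_start_mv and rms_end_mv must be > 0")
        if self.spectral_sigma_hz <= 0:
            raise ConfigurationError("spectral_sigma_hz must be > 0")
        if not 0 <= self.calib_duration_s < self.duration_s:
            raise ConfigurationError(
                f"calib_duration_s ({self.calib_duration_s}) must lie in "
                f"[0, duration_s={self.duration_s})"
            )
        if self.powerline_amp_mv < 0 or self.motion_artifact_amp_mv < 0:
            raise ConfigurationError("artifact amplitudes must be >= 0")
        if self.torque_coupling_ms < 0:
            raise ConfigurationError("torque_coupling_ms must be >= 0")


@dataclass
class SessionData:
    """One synchronized session: EMG (mV) and torque (Nm) on a common timebase."""

    emg: np.ndarray
    torque: np.ndarray
    calib_end_index: int
    sample_rate_hz: float

    def validate(self) -> None:
        if len(self.emg) != len(self.torque):
            raise DataError("emg and torque must have equal length")
        if not (np.all(np.isfinite(self.emg)) and np.all(np.isfinite(self.torque))):
            raise DataError("emg/torque contain non-finite values")
        if not 0 <= self.calib_end_index < len(self.emg):
            raise DataError(
                f"calib_end_index {self.calib_end_index} outside [0, {len(self.emg)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.emg)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


def _drifting_band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    f_start: float,
    f_end: float,
    sigma: float,
) -> np.ndarray:
    """Unit-RMS Gaussian noise whose spectral centroid drifts f_start → f_end."""
    burst = int(round(_BURST_S * fs))
    burst = min(burst, max(8, n))
    hop = burst // 2
    win = sps.windows.hann(burst, sym=False)
    freqs = np.fft.rfftfreq(burst, 1.0 / fs)
    out = np.zeros(n + 2 * burst)
    wss = np.zeros(n + 2 * burst)  # window power sum -> variance profile
    n_bursts = int(np.ceil(n / hop)) + 1
    for k in range(n_bursts):
        start = k * hop
        center = min(max((start + burst / 2) / max(n - 1, 1), 0.0), 1.0)
        fc = f_start + (f_end - f_start) * center
        band = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
        shaped = np.fft.irfft(np.fft.rfft(rng.standard_normal(burst)) * band, n=burst)
        std = shaped.std()
        if std > 0:
            shaped /= std
        out[start : start + burst] += win * shaped
        wss[start : start + burst] += win**2
    return out[:n] / np.sqrt(np.maximum(wss[:n], 1e-12))


def generate_session(config: SynthConfig) -> SessionData:
    """Synthesize one EMG + torque session from ``config``.

    Fixed ``config.seed`` gives bit-identical output. The relaxation segment
    is white noise at 5% of the initial active RMS; the active segment
    follows the drifting-band model described in the module docstring.
    """
    config.validate()
    fs = config.sample_rate_hz
    n_total = int(round(config.duration_s * fs))
    n_calib = int(round(config.calib_duration_s * fs))
    n_active = n_total - n_calib
    if n_active < 8:
        raise ConfigurationError("active segment too short (duration_s - calib_duration_s)")

    rng = np.random.default_rng(config.seed)

    active = _drifting_band_noise(
        rng, n_active, fs, config.mf_start_hz, config.mf_end_hz, config.spectral_sigma_hz
    )
    ramp = np.linspace(config.rms_start_mv, config.rms_end_mv, n_active)
    active *= ramp

    calib = rng.standard_normal(n_calib) * (_CALIB_RMS_FRAC * config.rms_start_mv)

    torque = np.zeros(n_total)
    schedule = np.linspace(config.torque_start_nm, config.torque_end_nm, n_active)
    if config.torque_coupling_ms > 0:
        from .sigproc import SmootherSpec, smooth

        activation = smooth(np.abs(active), fs, SmootherSpec(config.torque_coupling_ms))
        coupling = activation / ramp  # divide out the programmed RMS drift
        coupling /= coupling.mean()
        torque[n_calib:] = schedule * coupling
    else:
        torque[n_calib:] = schedule
    torque += rng.standard_normal(n_total) * (
        _TORQUE_NOISE_FRAC * abs(config.torque_start_nm)
    )

    session = SessionData(
        emg=np.concatenate([calib, active]),
        torque=torque,
        calib_end_index=n_calib,
        sample_rate_hz=fs,
    )
    session.validate()
    return session


def inject_artifacts(
    session: SessionData,
    powerline_amp_mv: float,
    motion_artifact_amp_mv: float,
    powerline_hz: float = 50.0,
    seed: int = 0,
) -> SessionData:
    """Contaminate a session with powerline and low-frequency motion artifacts.

    Adds a pure sinusoid at ``powerline_hz`` and band-limited (<10 Hz,
    4th-order low-pass at 5 Hz) Gaussian drift scaled to ``motion_artifact_amp_mv``
    RMS. Lengths and the torque trace are unchanged. Both amplitudes zero
    returns an identical copy.
    """
    if powerline_amp_mv < 0 or motion_artifact_amp_mv < 0:
        raise ConfigurationError("artifact amplitudes must be >= 0")
    session.validate()
    emg = session.emg.copy()
    n = len(emg)
    fs = session.sample_rate_hz
    if powerline_amp_mv > 0:
        t = np.arange(n) / fs
        emg = emg + powerline_amp_mv * np.sin(2 * np.pi * powerline_hz * t)
    if motion_artifact_amp_mv > 0:
        rng = np.random.default_rng(seed)
        sos = sps.butter(4, 5.0, btype="lowpass", fs=fs, output="sos")
        drift = sps.sosfilt(sos, rng.standard_normal(n))
        std = drift.std()
        if std > 0:
            drift = drift / std * motion_artifact_amp_mv
        emg = emg + drift
    return SessionData(
        emg=emg,
        torque=session.torque.copy(),
        calib_end_index=session.calib_end_index,
        sample_rate_hz=session.sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# CSV + YAML-sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path: pathlib.Path) -> pathlib.Path:
    return csv_path.with_suffix(csv_path.suffix + ".meta.yaml")


def write_session(
    session: SessionData, path: str | pathlib.Path, config: SynthConfig | None = None
) -> pathlib.Path:
    """Write ``time_s,emg_mv,torque_nm`` CSV plus a YAML sidecar with metadata."""
    import pandas as pd

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": session.times_s, "emg_mv": session.emg, "torque_nm": session.torque}
    ).to_csv(path, index=False)
    meta: dict = {
        "sample_rate_hz": float(session.sample_rate_hz),
        "calib_end_index": int(session.calib_end_index),
        "calib_end_s": session.calib_end_index / session.sample_rate_hz,
    }
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_session(path: str | pathlib.Path) -> SessionData:
    """Read a session written by :func:`write_session` (sidecar required)."""
    import pandas as pd

    path = pathlib.Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "emg_mv", "torque_nm"):
        if col not in df.columns:
            raise DataError(f"session CSV missing column {col!r}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise DataError(f"missing sidecar metadata file {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    session = SessionData(
        emg=df["emg_mv"].to_numpy(float),
        torque=df["torque_nm"].to_numpy(float),
        calib_end_index=int(meta["calib_end_index"]),
        sample_rate_hz=float(meta["sample_rate_hz"]),
    )
    session.validate()
    return session
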