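"""Three-state adaptive stimulation controller.

The SVM decision value (positive = Non-Fatigue side) is mapped onto three
fatigue levels by crisp thresholds, and each level has a stimulation
amplitude range:

- Low Fatigue      decision > +0.6     25-30 mA
- Moderate Fatigue -0.6 <= d <= +0.6   18-24 mA
- High Fatigue     decision < -0.6     12-17 mA

Stability machinery around the raw classification:

- **Hysteresis** — a transition requires the new state to be classified for
  at least ``hysteresis_windows`` (default 2) consecutive 200 ms windows; the
  candidate counter resets on any interruption. An optional secondary guard
  additionally requires the window MF to have moved >= 10% since the last
  transition (disabled by default).
- **Rate limiting** — at most one profile change per ``min_transition_interval_s``
  (default 15 s), measured from ramp start. A sustained candidate is held
  ready and fires once the interval elapses.
- **Ramping** — on transition the commanded amplitude ramps linearly from its
  current value to the new state's target over ``ramp_s`` (3-5 s, default 4).

The target amplitude within a state's range is, by default, an affine map of
the clamped decision value across the state's decision interval (more toward
the fatigued side => lower amplitude); a midpoint mode returns the range
center. The controller starts in Moderate at the range midpoint with the
rate-limit clock unset, so the first transition is never blocked.
"""

from __future__ import annotations

import math
import pathlib
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, DataError, TimingError

__all__ = [
    "FatigueState",
    "StimulationProfile",
    "ControllerConfig",
    "ControllerState",
    "StimulationCommand",
    "DEFAULT_PROFILES",
    "classify_state",
    "target_amplitude",
    "ramp_amplitude",
    "init_state",
    "step",
    "run_closed_loop",
    "commands_to_frame",
    "write_command_log",
    "read_command_log",
]


class FatigueState(str, Enum):
    LOW = "Low"
    MODERATE = "Moderate"
    HIGH = "High"


@dataclass(frozen=True)
class StimulationProfile:
    state: FatigueState
    amp_min_ma: float
    amp_max_ma: float

    def __post_init__(self) -> None:
        if not self.amp_min_ma < self.amp_max_ma:
            raise ConfigurationError(
                f"amp_min_ma must be < amp_max_ma, got "
                f"({self.amp_min_ma}, {self.amp_max_ma})"
            )

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.amp_min_ma + self.amp_max_ma)


DEFAULT_PROFILES: dict[FatigueState, StimulationProfile] = {
    FatigueState.LOW: StimulationProfile(FatigueState.LOW, 25.0, 30.0),
    FatigueState.MODERATE: StimulationProfile(FatigueState.MODERATE, 18.0, 24.0),
    FatigueState.HIGH: StimulationProfile(FatigueState.HIGH, 12.0, 17.0),
}


@dataclass
class ControllerConfig:
    upper_threshold: float = 0.6
    lower_threshold: float = -0.6
    hysteresis_windows: int = 2
    window_ms: float = 200.0
    step_ms: float = 100.0
    ramp_s: float = 4.0
    min_transition_interval_s: float = 15.0
    feature_hysteresis_frac: float = 0.10
    use_feature_hysteresis: bool = False
    #: decision values are clamped to [-decision_clamp, decision_clamp]
    #: when mapped onto an amplitude within a state's range
    decision_clamp: float = 2.0

    def validate(self) -> None:
        if not self.lower_threshold < self.upper_threshold:
            raise ConfigurationError("lower_threshold must be < upper_threshold")
        if not 3.0 <= self.ramp_s <= 5.0:
            raise ConfigurationError(f"ramp_s must lie in [3, 5] s, got {self.ramp_s}")
        if not self.min_transition_interval_s > self.ramp_s:
            raise ConfigurationError("min_transition_interval_s must exceed ramp_s")
        if self.hysteresis_windows < 1:
            raise ConfigurationError("hysteresis_windows must be >= 1")
        if self.decision_clamp < self.upper_threshold or -self.decision_clamp > self.lower_threshold:
            raise ConfigurationError("decision_clamp must cover both thresholds")
        if not 0 <= self.feature_hysteresis_frac < 1:
            raise ConfigurationError("feature_hysteresis_frac must be in [0, 1)")


@dataclass
class ControllerState:
    current: FatigueState
    candidate: FatigueState | None
    candidate_count: int
    last_transition_t: float
    commanded_amp_ma: float
    ramp: tuple[float, float, float] | None  # (t_start, amp_from, amp_to)
    last_t: float = -math.inf
    mf_at_last_transition: float | None = None


@dataclass(frozen=True)
class StimulationCommand:
    t_s: float
    state: FatigueState
    amplitude_ma: float
    event: str = "none"  # none | transition | ramp_end


def classify_state(decision: float, cfg: ControllerConfig | None = None) -> FatigueState:
    """Crisp threshold mapping; both boundaries belong to Moderate."""
    cfg = cfg or ControllerConfig()
    if not math.isfinite(decision):
        raise DataError(f"non-finite decision value: {decision}")
    if decision > cfg.upper_threshold:
        return FatigueState.LOW
    if decision < cfg.lower_threshold:
        return FatigueState.HIGH
    return FatigueState.MODERATE


def _decision_interval(state: FatigueState, cfg: ControllerConfig) -> tuple[float, float]:
    if state == FatigueState.LOW:
        return cfg.upper_threshold, cfg.decision_clamp
    if state == FatigueState.HIGH:
        return -cfg.decision_clamp, cfg.lower_threshold
    return cfg.lower_threshold, cfg.upper_threshold


def target_amplitude(
    state: FatigueState,
    decision: float,
    profiles: dict[FatigueState, StimulationProfile] | None = None,
    cfg: ControllerConfig | None = None,
    midpoint: bool = False,
) -> float:
    """Amplitude within the state's range for a given decision value.

    Default: affine map of the clamped decision across the state's decision
    interval onto [amp_min, amp_max] — the more fatigue-side the decision,
    the lower the amplitude. ``midpoint`` returns the range center.
    """
    profiles = profiles or DEFAULT_PROFILES
    cfg = cfg or ControllerConfig()
    prof = profiles[state]
    if midpoint:
        return prof.midpoint_ma
    d_lo, d_hi = _decision_interval(state, cfg)
    d = min(max(decision, d_lo), d_hi)
    frac = (d - d_lo) / (d_hi - d_lo)
    return prof.amp_min_ma + frac * (prof.amp_max_ma - prof.amp_min_ma)


def ramp_amplitude(amp0: float, amp1: float, ramp_s: float, elapsed_s: float) -> float:
    """Linear interpolation amp0 -> amp1 over ramp_s, clamped at amp1."""
    if not 3.0 <= ramp_s <= 5.0:
        raise ConfigurationError(f"ramp_s must lie in [3, 5] s, got {ramp_s}")
    if elapsed_s < 0:
        raise DataError("elapsed_s must be >= 0")
    if elapsed_s >= ramp_s:
        return amp1
    return amp0 + (amp1 - amp0) * (elapsed_s / ramp_s)


def init_state(
    cfg: ControllerConfig | None = None,
    profiles: dict[FatigueState, StimulationProfile] | None = None,
) -> ControllerState:
    """Start in Moderate at the range midpoint; rate-limit clock unset."""
    profiles = profiles or DEFAULT_PROFILES
    return ControllerState(
        current=FatigueState.MODERATE,
        candidate=None,
        candidate_count=0,
        last_transition_t=-math.inf,
        commanded_amp_ma=profiles[FatigueState.MODERATE].midpoint_ma,
        ramp=None,
    )


def step(
    state: ControllerState,
    decision: float,
    t: float,
    cfg: ControllerConfig | None = None,
    profiles: dict[FatigueState, StimulationProfile] | None = None,
    mf: float | None = None,
) -> tuple[ControllerState, StimulationCommand]:
    """Advance the controller by one feature window.

    Must be called with strictly increasing ``t`` (once per window step).
    Returns the new state and the stimulation command for this step.
    """
    cfg = cfg or ControllerConfig()
    profiles = profiles or DEFAULT_PROFILES
    cfg.validate()
    if t <= state.last_t:
        raise TimingError(f"non-monotone timestamp: {t} after {state.last_t}")

    classified = classify_state(decision, cfg)
    candidate, count = state.candidate, state.candidate_count
    if classified == state.current:
        candidate, count = None, 0
    elif classified == candidate:
        count = min(count + 1, cfg.hysteresis_windows)
    else:
        candidate, count = classified, 1

    current = state.current
    last_transition = state.last_transition_t
    ramp = state.ramp
    amp = state.commanded_amp_ma
    mf_ref = state.mf_at_last_transition
    event = "none"

    feature_guard_ok = True
    if cfg.use_feature_hysteresis and mf_ref is not None and mf_ref > 0 and mf is not None:
        feature_guard_ok = abs(mf - mf_ref) / mf_ref >= cfg.feature_hysteresis_frac

    if (
        candidate is not None
        and count >= cfg.hysteresis_windows
        and t - last_transition >= cfg.min_transition_interval_s
        and feature_guard_ok
    ):
        amp_target = target_amplitude(candidate, decision, profiles, cfg)
        ramp = (t, amp, amp_target)
        current = candidate
        candidate, count = None, 0
        last_transition = t  # rate-limit clock runs from ramp start
        mf_ref = mf if mf is not None else mf_ref
        event = "transition"

    if ramp is not None:
        t0, amp_from, amp_to = ramp
        amp = ramp_amplitude(amp_from, amp_to, cfg.ramp_s, t - t0)
        if t - t0 >= cfg.ramp_s:
            ramp = None
            if event == "none":
                event = "ramp_end"

    new_state = ControllerState(
        current=current,
        candidate=candidate,
        candidate_count=count,
        last_transition_t=last_transition,
        commanded_amp_ma=amp,
        ramp=ramp,
        last_t=t,
        mf_at_last_transition=mf_ref,
    )
    return new_state, StimulationCommand(t_s=t, state=current, amplitude_ma=amp, event=event)


def run_closed_loop(
    decisions: Sequence[float],
    cfg: ControllerConfig | None = None,
    profiles: dict[FatigueState, StimulationProfile] | None = None,
    t0: float = 0.0,
    mfs: Sequence[float] | None = None,
) -> list[StimulationCommand]:
    """Replay the controller over a per-window decision stream.

    Window ``i`` is stepped at ``t0 + i * cfg.step_ms / 1000``. ``mfs``
    optionally supplies per-window mean frequencies for the secondary
    feature-hysteresis guard.
    """
    cfg = cfg or ControllerConfig()
    profiles = profiles or DEFAULT_PROFILES
    if mfs is not None and len(mfs) != len(decisions):
        raise DataError("mfs not aligned to decisions")
    state = init_state(cfg, profiles)
    log: list[StimulationCommand] = []
    dt = cfg.step_ms / 1000.0
    for i, d in enumerate(decisions):
        mf = None if mfs is None else float(mfs[i])
        state, cmd = step(state, float(d), t0 + i * dt, cfg, profiles, mf=mf)
        log.append(cmd)
    return log


# ---------------------------------------------------------------------------
# Command-log I/O
# ---------------------------------------------------------------------------

def commands_to_frame(commands: Sequence[StimulationCommand]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": [c.t_s for c in commands],
            "state": [c.state.value for c in commands],
            "amplitude_ma": [c.amplitude_ma for c in commands],
            "event": [c.event for c in commands],
        }
    )


def write_command_log(
    commands: Sequence[StimulationCommand], path: str | pathlib.Path
) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    commands_to_frame(commands).to_csv(path, index=False)
    return path


def read_command_log(path: str | pathlib.Path) -> list[StimulationCommand]:
    df = pd.read_csv(path)
    missing = [c for c in ("t_s", "state", "amplitude_ma", "event") if c not in df.columns]
    if missing:
        raise DataError(f"command log missing columns {missing}")
    return [
        StimulationCommand(
            t_s=float(r.t_s),
            state=FatigueState(r.state),
            amplitude_ma=float(r.amplitude_ma),
            event=str(r.event),
        )
        for r in df.itertuples()
    ]
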