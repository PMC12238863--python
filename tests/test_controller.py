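"""Three-state controller: thresholds, hysteresis, rate limit, ramping, safety."""

import math

import numpy as np
import pytest

from fatigueloop import controller as ctl
from fatigueloop.errors import ConfigurationError, DataError, TimingError

CFG = ctl.ControllerConfig()
STEP_S = CFG.step_ms / 1000.0
AMP_RANGE = {
    ctl.FatigueState.LOW: (25.0, 30.0),
    ctl.FatigueState.MODERATE: (18.0, 24.0),
    ctl.FatigueState.HIGH: (12.0, 17.0),
}


def _transition_indices(commands):
    return [i for i, c in enumerate(commands) if c.event == "transition"]


def assert_rate_limited(commands, min_interval_s=15.0):
    """No sliding window of min_interval_s contains more than one transition."""
    times = [commands[i].t_s for i in _transition_indices(commands)]
    for a, b in zip(times, times[1:]):
        assert b - a >= min_interval_s


def assert_hysteresis_respected(commands, decisions, cfg=CFG):
    """Every transition is preceded by >= hysteresis_windows consecutive
    classifications equal to the new state."""
    classified = [ctl.classify_state(d, cfg) for d in decisions]
    for i in _transition_indices(commands):
        new_state = commands[i].state
        run = classified[max(0, i - cfg.hysteresis_windows + 1) : i + 1]
        assert all(s == new_state for s in run)


def assert_amplitudes_safe(commands, cfg=CFG):
    """Amplitude always in the 12-30 mA envelope and inside the active state's
    range once its ramp has completed."""
    ramp_end_t = -math.inf
    for c in commands:
        assert 12.0 <= c.amplitude_ma <= 30.0
        if c.event == "transition":
            ramp_end_t = c.t_s + cfg.ramp_s
        if c.t_s >= ramp_end_t:
            lo, hi = AMP_RANGE[c.state]
            assert lo <= c.amplitude_ma <= hi


class TestClassifyState:
    @pytest.mark.parametrize(
        "decision, expected",
        [
            (0.8, ctl.FatigueState.LOW),
            (0.61, ctl.FatigueState.LOW),
            (0.6, ctl.FatigueState.MODERATE),  # boundary inclusive to Moderate
            (0.0, ctl.FatigueState.MODERATE),
            (-0.6, ctl.FatigueState.MODERATE),
            (-0.61, ctl.FatigueState.HIGH),
        ],
    )
    def test_crisp_thresholds(self, decision, expected):
        assert ctl.classify_state(decision) == expected

    def test_nonfinite_decision_rejected(self):
        with pytest.raises(DataError):
            ctl.classify_state(float("nan"))


class TestStep:
    def test_two_consecutive_windows_trigger_transition(self):
        state = ctl.init_state()
        state, c1 = ctl.step(state, 0.7, 0.0)
        state, c2 = ctl.step(state, 0.7, 0.1)
        assert c1.event == "none" and c1.state == ctl.FatigueState.MODERATE
        assert c2.event == "transition" and c2.state == ctl.FatigueState.LOW

    def test_interrupted_run_resets_the_counter(self):
        state = ctl.init_state()
        events = []
        for t, d in enumerate([0.7, 0.5, 0.7]):
            state, cmd = ctl.step(state, d, t * 0.1)
            events.append(cmd.event)
        assert events == ["none"] * 3
        assert state.current == ctl.FatigueState.MODERATE

    def test_rate_limit_defers_transition_until_interval_elapsed(self):
        state = ctl.init_state()
        # force a transition at t = 100 s
        state, _ = ctl.step(state, 0.7, 99.9)
        state, cmd = ctl.step(state, 0.7, 100.0)
        assert cmd.event == "transition"
        # sustained High decisions from t = 105 s: held until t >= 115 s
        t = 105.0
        transition_t = None
        while t < 116.0:
            state, cmd = ctl.step(state, -0.9, t)
            if cmd.event == "transition":
                transition_t = t
                break
            t = round(t + 0.1, 10)
        assert transition_t is not None
        assert transition_t >= 115.0
        assert transition_t == pytest.approx(115.0, abs=0.1001)

    def test_candidate_counter_never_exceeds_hysteresis_windows(self):
        state = ctl.init_state()
        for i in range(50):
            state, _ = ctl.step(state, -0.9, i * 0.1)
            assert state.candidate_count <= CFG.hysteresis_windows

    def test_nonmonotone_time_rejected(self):
        state = ctl.init_state()
        state, _ = ctl.step(state, 0.0, 1.0)
        with pytest.raises(TimingError):
            ctl.step(state, 0.0, 1.0)


class TestRamp:
    def test_linear_interpolation_endpoints_and_midpoint(self):
        assert ctl.ramp_amplitude(27, 20, 4.0, 0.0) == 27
        assert ctl.ramp_amplitude(27, 20, 4.0, 2.0) == pytest.approx(23.5)
        assert ctl.ramp_amplitude(27, 20, 4.0, 10.0) == 20  # clamped

    def test_ramp_duration_outside_three_to_five_seconds_rejected(self):
        with pytest.raises(ConfigurationError):
            ctl.ramp_amplitude(27, 20, 2.0, 1.0)


class TestTargetAmplitude:
    def test_high_state_clamp_bound_maps_to_range_floor(self):
        assert ctl.target_amplitude(ctl.FatigueState.HIGH, -2.0) == pytest.approx(12.0)

    def test_moderate_neutral_decision_maps_to_range_centre(self):
        assert ctl.target_amplitude(ctl.FatigueState.MODERATE, 0.0) == pytest.approx(21.0)

    def test_midpoint_mode(self):
        assert ctl.target_amplitude(
            ctl.FatigueState.LOW, 1.3, midpoint=True
        ) == pytest.approx(27.5)

    def test_more_fatigued_decisions_get_lower_amplitude(self):
        a = ctl.target_amplitude(ctl.FatigueState.MODERATE, -0.5)
        b = ctl.target_amplitude(ctl.FatigueState.MODERATE, +0.5)
        assert a < b


class TestClosedLoop:
    def test_stationary_neutral_stream_never_transitions(self):
        commands = ctl.run_closed_loop([0.0] * 600)  # 60 s
        assert {c.state for c in commands} == {ctl.FatigueState.MODERATE}
        assert _transition_indices(commands) == []

    def test_alternating_extremes_cannot_chatter(self):
        decisions = [0.7 if i % 2 == 0 else -0.7 for i in range(6000)]  # 10 min
        commands = ctl.run_closed_loop(decisions)
        assert_rate_limited(commands)
        assert_hysteresis_respected(commands, decisions)
        # strict alternation never yields two consecutive same-state windows
        assert _transition_indices(commands) == []

    def test_adversarial_block_stream_is_rate_limited_and_safe(self):
        # blocks of 3 windows alternating Low/High pressure: transition
        # attempts fire constantly, the limiter must hold one per 15 s
        decisions = []
        for block in range(2000):  # 6000 windows = 10 min
            decisions.extend([0.9 if block % 2 == 0 else -0.9] * 3)
        commands = ctl.run_closed_loop(decisions)
        transitions = _transition_indices(commands)
        assert len(transitions) >= 2
        assert_rate_limited(commands)
        assert_hysteresis_respected(commands, decisions)
        assert_amplitudes_safe(commands)

    def test_random_decision_stream_safety_envelope(self):
        rng = np.random.default_rng(123)
        decisions = rng.normal(0.0, 1.2, size=6000)
        commands = ctl.run_closed_loop(decisions)
        assert_rate_limited(commands)
        assert_hysteresis_respected(commands, decisions)
        assert_amplitudes_safe(commands)

    def test_ramp_changes_amplitude_without_step_discontinuities(self):
        decisions = [0.9] * 300  # one Moderate->Low transition, then hold
        commands = ctl.run_closed_loop(decisions)
        amps = np.array([c.amplitude_ma for c in commands])
        span = 30.0 - 12.0
        max_step = span / (CFG.ramp_s / STEP_S)
        assert np.abs(np.diff(amps)).max() <= max_step + 1e-9

    def test_ramp_end_event_emitted_once_per_transition(self):
        decisions = [0.9] * 300
        commands = ctl.run_closed_loop(decisions)
        events = [c.event for c in commands]
        assert events.count("transition") == 1
        assert events.count("ramp_end") == 1
        assert events.index("ramp_end") > events.index("transition")


def test_command_log_roundtrip(tmp_path):
    commands = ctl.run_closed_loop([0.9] * 50 + [-0.9] * 50)
    path = ctl.write_command_log(commands, tmp_path / "log.csv")
    back = ctl.read_command_log(path)
    assert [c.state for c in back] == [c.state for c in commands]
    assert [c.event for c in back] == [c.event for c in commands]
    np.testing.assert_allclose(
        [c.amplitude_ma for c in back], [c.amplitude_ma for c in commands], rtol=1e-12
    )


def test_feature_hysteresis_guard_blocks_static_mf_transitions():
    cfg = ctl.ControllerConfig(use_feature_hysteresis=True)
    # first transition allowed (no reference yet); afterwards MF stays within
    # 10% of its value at that transition, so the reversal is suppressed
    decisions = [0.9] * 160 + [-0.9] * 160
    mfs = [80.0] * 320
    commands = ctl.run_closed_loop(decisions, cfg, mfs=mfs)
    assert len(_transition_indices(commands)) == 1
    # with a genuine >= 10% MF shift the reversal goes through
    mfs_shifted = [80.0] * 160 + [70.0] * 160
    commands = ctl.run_closed_loop(decisions, cfg, mfs=mfs_shifted)
    assert len(_transition_indices(commands)) == 2
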