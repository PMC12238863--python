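"""RPF, percent change, exact Wilcoxon signed-rank, and report generation."""

import itertools
import json
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from fatigueloop import controller as ctl
from fatigueloop import report as rp
from fatigueloop.errors import ConfigurationError, DataError


class TestRpf:
    @pytest.mark.parametrize(
        "rom_post, expected",
        [(82.0, 9.1), (90.0, 10.0), (63.0, 7.0), (55.0, 6.1), (0.0, 0.0)],
    )
    def test_worked_examples_to_one_decimal(self, rom_post, expected):
        assert rp.rpf_score(rom_post, 90.0) == expected

    def test_unrounded_value_retained(self):
        assert rp.rpf(82.0, 90.0) == pytest.approx(82 / 90 * 10)

    def test_negative_rom_rejected(self):
        with pytest.raises(DataError):
            rp.rpf(-5.0)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ConfigurationError):
            rp.rpf(80.0, 0.0)

    @given(st.floats(0.1, 180.0), st.floats(10.0, 180.0), st.floats(0.5, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_rom_and_scale_invariant(self, rom, target, k):
        assert rp.rpf(2 * rom, target) == pytest.approx(2 * rp.rpf(rom, target))
        assert rp.rpf(k * rom, k * target) == pytest.approx(rp.rpf(rom, target))


class TestPercentChange:
    def test_patient_one_torque_arithmetic(self):
        assert rp.round_half_up(rp.percent_change(0.91, 1.42), 1) == 56.0
        assert rp.round_half_up(rp.percent_change(0.39, 0.23), 1) == -41.0

    def test_no_change_is_zero(self):
        assert rp.percent_change(3.3, 3.3) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(DataError):
            rp.percent_change(0.0, 1.0)


def _brute_force_two_sided_p(diffs):
    """Independent enumeration oracle: count sign assignments directly."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = spstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    eps = 1e-9
    p_le = sum(s <= w_obs + eps for s in sums) / len(sums)
    p_ge = sum(s >= w_obs - eps for s in sums) / len(sums)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonExact:
    def test_three_uniform_sign_differences(self):
        res = rp.wilcoxon_exact([1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(0.25)
        assert res.statistic == 6.0

    def test_enumeration_examples(self):
        assert rp.wilcoxon_exact([1.0, 2.0, -3.0]).p_value == pytest.approx(1.0)
        assert rp.wilcoxon_exact([5.0, 1.0, -2.0]).p_value == pytest.approx(0.75)

    def test_pre_post_interface_matches_difference_interface(self):
        pre, post = [10.0, 12.0, 9.0], [12.0, 15.0, 13.0]
        a = rp.wilcoxon_exact(pre, post)
        b = rp.wilcoxon_exact(np.array(post) - np.array(pre))
        assert a.p_value == b.p_value and a.statistic == b.statistic

    @pytest.mark.parametrize("n", range(3, 9))
    def test_matches_brute_force_oracle_for_all_sign_patterns(self, n):
        rng = np.random.default_rng(n)
        magnitudes = rng.uniform(0.5, 10.0, size=n)
        for signs in itertools.product([-1.0, 1.0], repeat=n):
            diffs = magnitudes * np.array(signs)
            ours = rp.wilcoxon_exact(diffs).p_value
            assert ours == pytest.approx(_brute_force_two_sided_p(diffs))

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_matches_scipy_exact_on_tie_free_data(self, n):
        rng = np.random.default_rng(100 + n)
        diffs = rng.normal(0.4, 1.0, size=n)
        expected = spstats.wilcoxon(diffs, method="exact").pvalue
        assert rp.wilcoxon_exact(diffs).p_value == pytest.approx(expected)

    def test_tied_magnitudes_use_midranks(self):
        res = rp.wilcoxon_exact([1.0, 1.0, -1.0])  # midranks (2, 2, 2)
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(_brute_force_two_sided_p([1.0, 1.0, -1.0]))

    def test_zero_differences_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero difference"):
            res = rp.wilcoxon_exact([0.0, 1.0, 2.0])
        assert res.n == 2 and res.n_zeros_dropped == 1

    def test_all_zero_differences_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(DataError):
                rp.wilcoxon_exact([0.0, 0.0])

    def test_large_n_rejected(self):
        with pytest.raises(DataError):
            rp.wilcoxon_exact(np.arange(1.0, 18.0))


def _three_patients():
    """Synthetic cohort built around the study's printed post values; the
    pre-intervention RoM values are synthetic stand-ins (not printed)."""
    return [
        rp.OutcomeRecord("P1", 57.0, 82.0, 0.91, 1.42, 0.39, 0.23),
        rp.OutcomeRecord("P2", 44.0, 63.0, 0.66, 0.97, 0.47, 0.30),
        rp.OutcomeRecord("P3", 38.0, 55.0, 0.53, 0.77, 0.45, 0.29),
    ]


class TestGenerateReport:
    def test_rpf_column_for_printed_post_roms(self):
        report = rp.generate_report(_three_patients())
        assert [p["rpf"] for p in report["patients"]] == [9.1, 7.0, 6.1]

    def test_consistent_group_direction_gives_smallest_exact_p(self):
        # three same-direction changes: two-sided exact p = 2/8 = 0.25 per metric
        report = rp.generate_report(_three_patients())
        for metric in report["group"]["metrics"].values():
            assert metric["wilcoxon_p"] == pytest.approx(0.25)

    def test_degenerate_no_change_patient_skips_test_with_note(self):
        rec = rp.OutcomeRecord("P1", 50.0, 50.0, 1.0, 1.0, 0.4, 0.4)
        report = rp.generate_report([rec])
        for metric in report["group"]["metrics"].values():
            assert metric["wilcoxon_p"] is None
            assert "skipped" in metric["note"]
        for p in report["patients"]:
            assert p["rom_deg"]["percent_change"] == 0.0

    def test_markdown_and_json_agree_on_numbers(self, tmp_path):
        report = rp.generate_report(_three_patients())
        json_path, md_path = rp.write_report(report, tmp_path)
        loaded = json.loads(json_path.read_text())
        md = md_path.read_text()
        for p in loaded["patients"]:
            row = next(l for l in md.splitlines() if l.startswith(f"| {p['patient_id']} "))
            cells = [c.strip() for c in row.strip("|").split("|")]
            assert float(cells[-1]) == p["rpf"]
            assert float(cells[3]) == p["rom_deg"]["percent_change"]
        for metric in loaded["group"]["metrics"].values():
            assert re.search(rf"Wilcoxon two-sided p = {metric['wilcoxon_p']:g}", md)

    def test_missing_field_names_patient_and_field(self):
        rec = rp.OutcomeRecord("P9", 50.0, float("nan"), 1.0, 1.2, 0.4, 0.3)
        with pytest.raises(DataError, match=r"P9.*rom_post_deg"):
            rp.generate_report([rec])

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataError):
            rp.generate_report([])

    def test_command_log_summary_included(self):
        commands = ctl.run_closed_loop([0.9] * 160 + [-0.9] * 160)
        report = rp.generate_report(_three_patients(), {"session1": commands})
        s = report["sessions"]["session1"]
        assert s["n_steps"] == 320
        assert s["n_transitions"] >= 1
        assert sum(s["time_in_state_frac"].values()) == pytest.approx(1.0)


def test_outcomes_csv_roundtrip(tmp_path):
    path = tmp_path / "outcomes.csv"
    path.write_text(
        "patient_id,rom_pre_deg,rom_post_deg,at_pre_nm,at_post_nm,pt_pre_nm,pt_post_nm\n"
        "P1,57,82,0.91,1.42,0.39,0.23\n"
    )
    records = rp.read_outcomes_csv(path)
    assert records[0].patient_id == "P1"
    assert records[0].rom_post_deg == 82.0


def test_outcomes_csv_missing_column_rejected(tmp_path):
    path = tmp_path / "outcomes.csv"
    path.write_text("patient_id,rom_pre_deg\nP1,57\n")
    with pytest.raises(DataError, match="missing columns"):
        rp.read_outcomes_csv(path)
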