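"""Session and outcome reporting: RPF, percent changes, exact Wilcoxon, reports.

The Rehabilitation Progress Factor (RPF) summarizes joint-mobility progress
as ``RPF = RoM_post / RoM_target * 10`` on a 0-10 scale, with the clinical
target RoM defaulting to 90 degrees. Displayed values are rounded half-up to
one decimal; the unrounded value is retained for computation.

Group comparisons use an exact small-sample Wilcoxon signed-rank test: with
n paired differences (zeros dropped, midranks for tied magnitudes) the null
distribution of W+ is obtained by full enumeration of the 2^n sign
assignments, and the two-sided p-value is the doubled smaller tail capped at
1. With n = 3 same-sign differences this yields p = 2 * (1/8) = 0.25, the
smallest two-sided p attainable at that sample size.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .controller import FatigueState, StimulationCommand
from .errors import ConfigurationError, DataError

__all__ = [
    "ROM_TARGET_DEG_DEFAULT",
    "OutcomeRecord",
    "WilcoxonResult",
    "rpf",
    "rpf_score",
    "round_half_up",
    "percent_change",
    "wilcoxon_exact",
    "read_outcomes_csv",
    "summarize_commands",
    "generate_report",
    "render_markdown",
    "write_report",
]

ROM_TARGET_DEG_DEFAULT = 90.0

_OUTCOME_COLUMNS = {
    "rom_pre_deg": "rom_pre_deg",
    "rom_post_deg": "rom_post_deg",
    "at_pre_nm": "active_torque_pre_nm",
    "at_post_nm": "active_torque_post_nm",
    "pt_pre_nm": "passive_torque_pre_nm",
    "pt_post_nm": "passive_torque_post_nm",
}


@dataclass
class OutcomeRecord:
    """Pre/post clinical measurements for one patient."""

    patient_id: str
    rom_pre_deg: float
    rom_post_deg: float
    active_torque_pre_nm: float
    active_torque_post_nm: float
    passive_torque_pre_nm: float
    passive_torque_post_nm: float

    def validate(self) -> None:
        for name in (
            "rom_pre_deg",
            "rom_post_deg",
            "active_torque_pre_nm",
            "active_torque_post_nm",
            "passive_torque_pre_nm",
            "passive_torque_post_nm",
        ):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise DataError(f"patient {self.patient_id}: field {name} missing or non-finite")
        for name in ("rom_pre_deg", "rom_post_deg"):
            v = getattr(self, name)
            if not 0 <= v <= 180:
                raise DataError(
                    f"patient {self.patient_id}: {name}={v} outside [0, 180] degrees"
                )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (display convention for RPF and percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rpf(rom_post_deg: float, rom_target_deg: float = ROM_TARGET_DEG_DEFAULT) -> float:
    """Unrounded Rehabilitation Progress Factor on the 0-10 scale."""
    if rom_target_deg <= 0:
        raise ConfigurationError(f"rom_target_deg must be > 0, got {rom_target_deg}")
    if rom_post_deg < 0:
        raise DataError(f"rom_post_deg must be >= 0, got {rom_post_deg}")
    return rom_post_deg / rom_target_deg * 10.0


def rpf_score(rom_post_deg: float, rom_target_deg: float = ROM_TARGET_DEG_DEFAULT) -> float:
    """RPF rounded half-up to one decimal — the reported form."""
    return round_half_up(rpf(rom_post_deg, rom_target_deg), 1)


def percent_change(pre: float, post: float) -> float:
    """Signed percent change (post - pre) / pre * 100; positive = increase."""
    if pre == 0:
        raise DataError("percent change undefined for pre = 0")
    return (post - pre) / pre * 100.0


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n: int  # differences used after zero-dropping
    n_zeros_dropped: int


def wilcoxon_exact(
    pre: Sequence[float],
    post: Sequence[float] | None = None,
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test by full 2^n enumeration.

    Call with paired ``(pre, post)`` samples (differences are post - pre) or
    with a single array of differences. Zero differences are dropped with a
    warning. Tied magnitudes receive midranks. Restricted to n <= 15 where
    exhaustive enumeration is the exact reference.
    """
    if post is not None:
        pre_a = np.asarray(pre, float)
        post_a = np.asarray(post, float)
        if pre_a.shape != post_a.shape:
            raise DataError("pre and post must have equal length")
        diffs = post_a - pre_a
    else:
        diffs = np.asarray(pre, float)
    if not np.all(np.isfinite(diffs)):
        raise DataError("differences contain non-finite values")

    nonzero = diffs[diffs != 0]
    n_dropped = len(diffs) - len(nonzero)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} zero difference(s); n reduced to {len(nonzero)}",
            UserWarning,
            stacklevel=2,
        )
    n = len(nonzero)
    if n == 0:
        raise DataError("no nonzero differences; Wilcoxon test undefined")
    if n > 15:
        raise DataError(f"exact enumeration supported for n <= 15, got {n}")

    ranks = spstats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())

    # all 2^n subset sums of the ranks = exact null distribution of W+
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    p_le = float(np.mean(sums <= w_plus + eps))
    p_ge = float(np.mean(sums >= w_plus - eps))
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(statistic=w_plus, p_value=p, n=n, n_zeros_dropped=n_dropped)


def read_outcomes_csv(path: str | pathlib.Path) -> list[OutcomeRecord]:
    """Read `patient_id,rom_pre_deg,rom_post_deg,at_pre_nm,at_post_nm,pt_pre_nm,pt_post_nm`."""
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", *_OUTCOME_COLUMNS) if c not in df.columns]
    if missing:
        raise DataError(f"outcomes CSV missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        rec = OutcomeRecord(
            patient_id=str(row["patient_id"]),
            **{field: float(row[col]) for col, field in _OUTCOME_COLUMNS.items()},
        )
        rec.validate()
        records.append(rec)
    return records


def summarize_commands(commands: Sequence[StimulationCommand]) -> dict:
    """Transition count, time-in-state fractions and final command of a log."""
    if not commands:
        return {"n_steps": 0, "n_transitions": 0, "time_in_state_frac": {}, "final_state": None}
    states = [c.state for c in commands]
    counts = {s.value: states.count(s) for s in FatigueState}
    total = len(states)
    return {
        "n_steps": total,
        "n_transitions": sum(1 for c in commands if c.event == "transition"),
        "time_in_state_frac": {k: v / total for k, v in counts.items()},
        "final_state": commands[-1].state.value,
        "final_amplitude_ma": commands[-1].amplitude_ma,
    }


_METRICS = (
    ("rom_deg", "rom_pre_deg", "rom_post_deg", "Range of motion (deg)"),
    ("active_torque_nm", "active_torque_pre_nm", "active_torque_post_nm", "Active torque (Nm)"),
    ("passive_torque_nm", "passive_torque_pre_nm", "passive_torque_post_nm", "Passive torque (Nm)"),
)


def generate_report(
    records: Sequence[OutcomeRecord],
    command_logs: Mapping[str, Sequence[StimulationCommand]] | None = None,
    metadata: Mapping | None = None,
    rom_target_deg: float = ROM_TARGET_DEG_DEFAULT,
) -> dict:
    """Build the structured (JSON-serializable) progress report.

    Per patient: pre/post metrics, percent changes and the RPF. Group level:
    mean percent change and the exact Wilcoxon two-sided p per metric; the
    test is skipped with a note when all differences are zero. Controller
    logs, when supplied, contribute per-session summaries.
    """
    if not records:
        raise DataError("at least one patient record is required")
    for rec in records:
        rec.validate()

    patients = []
    for rec in records:
        entry: dict = {"patient_id": rec.patient_id}
        for key, pre_f, post_f, _ in _METRICS:
            pre, post = getattr(rec, pre_f), getattr(rec, post_f)
            entry[key] = {
                "pre": pre,
                "post": post,
                "percent_change": round_half_up(percent_change(pre, post), 1),
            }
        entry["rpf"] = rpf_score(rec.rom_post_deg, rom_target_deg)
        patients.append(entry)

    group: dict = {"n_patients": len(records), "rom_target_deg": rom_target_deg, "metrics": {}}
    for key, pre_f, post_f, _ in _METRICS:
        pre = np.array([getattr(r, pre_f) for r in records], float)
        post = np.array([getattr(r, post_f) for r in records], float)
        changes = [percent_change(a, b) for a, b in zip(pre, post)]
        metric: dict = {"mean_percent_change": round_half_up(float(np.mean(changes)), 1)}
        if np.all(post - pre == 0):
            metric["wilcoxon_p"] = None
            metric["note"] = "all pre/post differences are zero; signed-rank test skipped"
        else:
            res = wilcoxon_exact(pre, post)
            metric["wilcoxon_p"] = res.p_value
            metric["wilcoxon_statistic"] = res.statistic
        group["metrics"][key] = metric

    report = {"patients": patients, "group": group}
    if command_logs:
        report["sessions"] = {
            str(k): summarize_commands(v) for k, v in command_logs.items()
        }
    if metadata:
        report["metadata"] = dict(metadata)
    return report


def render_markdown(report: dict) -> str:
    """Human-readable Markdown view of :func:`generate_report` output.

    Every number is formatted from the same dict the JSON serializes, so the
    two artifacts cannot disagree.
    """
    lines = ["# Rehabilitation session report", ""]
    lines.append("## Patients")
    lines.append("")
    lines.append(
        "| Patient | RoM pre (deg) | RoM post (deg) | RoM change (%) | "
        "Active torque pre/post (Nm) | AT change (%) | "
        "Passive torque pre/post (Nm) | PT change (%) | RPF (0-10) |"
    )
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for p in report["patients"]:
        rom, at, pt = p["rom_deg"], p["active_torque_nm"], p["passive_torque_nm"]
        lines.append(
            f"| {p['patient_id']} | {rom['pre']:g} | {rom['post']:g} | "
            f"{rom['percent_change']:g} | {at['pre']:g}/{at['post']:g} | "
            f"{at['percent_change']:g} | {pt['pre']:g}/{pt['post']:g} | "
            f"{pt['percent_change']:g} | {p['rpf']:g} |"
        )
    lines.append("")
    g = report["group"]
    lines.append(f"## Group (n = {g['n_patients']}, target RoM {g['rom_target_deg']:g} deg)")
    lines.append("")
    for key, _, _, title in _METRICS:
        m = g["metrics"][key]
        p_txt = "skipped" if m["wilcoxon_p"] is None else f"{m['wilcoxon_p']:g}"
        lines.append(
            f"- {title}: mean change {m['mean_percent_change']:g}%, "
            f"Wilcoxon two-sided p = {p_txt}"
        )
        if m.get("note"):
            lines.append(f"  - note: {m['note']}")
    if "sessions" in report:
        lines.append("")
        lines.append("## Controller sessions")
        lines.append("")
        for name, s in report["sessions"].items():
            frac = ", ".join(f"{k}: {v:.3f}" for k, v in s["time_in_state_frac"].items())
            lines.append(
                f"- {name}: {s['n_transitions']} transition(s) over {s['n_steps']} steps; "
                f"time in state — {frac}; final state {s['final_state']}"
            )
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, outdir: str | pathlib.Path) -> tuple[pathlib.Path, pathlib.Path]:
    """Write report.json and report.md into ``outdir``; returns both paths."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    md_path = outdir / "report.md"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    md_path.write_text(render_markdown(report))
    return json_path, md_path
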