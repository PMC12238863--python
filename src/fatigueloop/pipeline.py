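"""End-to-end orchestration: simulate → preprocess → features → model → control → report.

This single-process loop reproduces the dataflow of the real-time system
(acquisition → signal processing/decision → actuation) with the same data
contracts; each stage writes a self-describing artifact (CSV/JSON with
headers or sidecar metadata) so any stage can be re-run from the previous
stage's files alone. Stage boundaries are logged with parameters and a
SHA-256 content hash of each written file under the ``fatigueloop.<stage>``
logger channels.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``; each child state is reduced
modulo 2**31 to a plain integer. Fixed seed => byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import controller as ctl
from . import fatigue_model as fm
from . import features as ft
from . import report as rp
from . import sigproc as sp
from . import synthgen as sg
from .errors import ConfigurationError

__all__ = ["SvmParams", "PipelineConfig", "PipelineResult", "split_seed", "run_pipeline"]

log = logging.getLogger("fatigueloop.pipeline")


@dataclass
class SvmParams:
    C: float = 1.0
    gamma: float | str = "scale"


@dataclass
class PipelineConfig:
    synth: sg.SynthConfig = field(default_factory=sg.SynthConfig)
    filter: sp.FilterSpec = field(default_factory=sp.FilterSpec)
    smoother: sp.SmootherSpec = field(default_factory=sp.SmootherSpec)
    window: ft.WindowSpec = field(default_factory=ft.WindowSpec)
    labeling: ft.LabelingConfig = field(default_factory=ft.LabelingConfig)
    svm: SvmParams = field(default_factory=SvmParams)
    controller: ctl.ControllerConfig = field(default_factory=ctl.ControllerConfig)
    seed: int = 0
    outdir: str = "fatigueloop_out"
    paper_strict: bool = False
    cv_folds: int = 5
    #: ZC deadband as a multiple of the calibration-segment RMS
    zc_deadband_calib_rms_mult: float = 3.0

    def validate(self) -> None:
        self.synth.validate()
        self.filter.validate(self.synth.sample_rate_hz)
        self.smoother.validate()
        self.window.validate()
        self.labeling.validate()
        self.controller.validate()
        if self.controller.window_ms != self.window.window_ms:
            raise ConfigurationError(
                f"controller.window_ms ({self.controller.window_ms}) must match "
                f"window.window_ms ({self.window.window_ms})"
            )
        if self.controller.step_ms != self.window.step_ms:
            raise ConfigurationError(
                f"controller.step_ms ({self.controller.step_ms}) must match "
                f"window.step_ms ({self.window.step_ms})"
            )
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter"]["mode"] = self.filter.mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "synth" in d:
            kwargs["synth"] = sg.SynthConfig(**d.pop("synth"))
        if "filter" in d:
            f = dict(d.pop("filter"))
            if "mode" in f:
                f["mode"] = sp.FilterMode(f["mode"])
            kwargs["filter"] = sp.FilterSpec(**f)
        if "smoother" in d:
            kwargs["smoother"] = sp.SmootherSpec(**d.pop("smoother"))
        if "window" in d:
            kwargs["window"] = ft.WindowSpec(**d.pop("window"))
        if "labeling" in d:
            kwargs["labeling"] = ft.LabelingConfig(**d.pop("labeling"))
        if "svm" in d:
            kwargs["svm"] = SvmParams(**d.pop("svm"))
        if "controller" in d:
            kwargs["controller"] = ctl.ControllerConfig(**d.pop("controller"))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | pathlib.Path) -> pathlib.Path:
        path = pathlib.Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()) or {})


def split_seed(seed: int, n: int) -> list[int]:
    """Fan one global seed out to ``n`` independent stage seeds (< 2**31)."""
    return [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(seed).spawn(n)
    ]


@dataclass
class PipelineResult:
    paths: dict
    session: sg.SessionData
    features: list[ft.FeatureWindow]
    labels: list[ft.FatigueLabel]
    model: fm.SvmModel | None
    cv: fm.CVResult | None
    decisions: np.ndarray
    commands: list[ctl.StimulationCommand]
    report: dict


def _log_artifact(stage: str, path: pathlib.Path, **params) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    logging.getLogger(f"fatigueloop.{stage}").info(
        "%s sha256=%s params=%s", path.name, digest, params
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full offline loop; fixed ``cfg.seed`` gives identical artifacts.

    When the labeler produces a single class (e.g. drift-free sessions) the
    classifier cannot be trained; the controller is then replayed on neutral
    decisions (0.0, inside the Moderate band) and stays in its initial state.
    """
    cfg.validate()
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_synth, seed_artifacts, seed_cv = split_seed(cfg.seed, 3)
    paths: dict = {}

    # -- acquisition --------------------------------------------------------
    synth_cfg = dataclasses.replace(cfg.synth, seed=seed_synth)
    session = sg.generate_session(synth_cfg)
    if synth_cfg.powerline_amp_mv > 0 or synth_cfg.motion_artifact_amp_mv > 0:
        session = sg.inject_artifacts(
            session,
            synth_cfg.powerline_amp_mv,
            synth_cfg.motion_artifact_amp_mv,
            powerline_hz=synth_cfg.powerline_hz,
            seed=seed_artifacts,
        )
    paths["session"] = sg.write_session(session, outdir / "session.csv", synth_cfg)
    _log_artifact("acquisition", paths["session"], seed=seed_synth)

    # -- signal processing ---------------------------------------------------
    fs = session.sample_rate_hz
    bp = sp.bandpass(session.emg, fs, cfg.filter)
    env = sp.smooth(sp.rectify(bp), fs, cfg.smoother)
    import pandas as pd

    pre_df = pd.DataFrame(
        {
            "time_s": session.times_s,
            "emg_bp_mv": bp,
            "envelope_mv": env,
            "torque_nm": session.torque,
        }
    )
    paths["preprocessed"] = outdir / "preprocessed.csv"
    pre_df.to_csv(paths["preprocessed"], index=False)
    _log_artifact(
        "sigproc",
        paths["preprocessed"],
        band=(cfg.filter.low_cut_hz, cfg.filter.high_cut_hz),
        order=cfg.filter.order,
        mode=cfg.filter.mode.value,
        smooth_ms=cfg.smoother.window_ms,
    )

    # -- features + labels ---------------------------------------------------
    i0 = session.calib_end_index
    calib_rms = float(np.sqrt(np.mean(bp[:i0] ** 2))) if i0 > 0 else 0.0
    deadband = cfg.zc_deadband_calib_rms_mult * calib_rms
    windows = ft.extract_feature_table(
        bp[i0:],
        env[i0:],
        fs,
        cfg.window,
        zc_deadband_mv=deadband,
        t_offset_s=i0 / fs,
        paper_strict=cfg.paper_strict,
    )
    window_torque = ft.window_means(session.torque[i0:], fs, cfg.window)
    labels = ft.label_windows(windows, window_torque, cfg.labeling)
    paths["features"] = ft.write_feature_table(windows, outdir / "features.csv", labels)
    _log_artifact("features", paths["features"], deadband_mv=deadband, n_windows=len(windows))

    # -- decision model ------------------------------------------------------
    X = ft.feature_matrix(windows)
    y = np.array([l.label for l in labels])
    class_counts = {str(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    model: fm.SvmModel | None = None
    cv: fm.CVResult | None = None
    if len(class_counts) == 2:
        model = fm.train_svm(X, y, C=cfg.svm.C, gamma=cfg.svm.gamma)
        paths["model"] = fm.save_model(model, outdir / "model.json")
        _log_artifact("model", paths["model"], C=cfg.svm.C, gamma=cfg.svm.gamma)
        if min(class_counts.values()) >= cfg.cv_folds:
            cv = fm.cross_validate(
                X, y, k=cfg.cv_folds, seed=seed_cv, C=cfg.svm.C, gamma=cfg.svm.gamma
            )
        decisions = model.decision_function(X)
    else:
        log.info("single-class labels %s; controller replayed on neutral decisions", class_counts)
        decisions = np.zeros(len(windows))

    # -- actuation (offline replay) -------------------------------------------
    commands = ctl.run_closed_loop(
        decisions,
        cfg.controller,
        t0=windows[0].t_start_s if windows else 0.0,
        mfs=[w.mf for w in windows],
    )
    paths["commands"] = ctl.write_command_log(commands, outdir / "commands.csv")
    _log_artifact("actuation", paths["commands"], n_steps=len(commands))

    # -- session report --------------------------------------------------------
    session_report = {
        "session": {
            "n_windows": len(windows),
            "label_counts": class_counts,
            "fatigue_fraction": class_counts.get(ft.FATIGUE, 0) / max(len(windows), 1),
            "cv_mean_accuracy": None if cv is None else cv.mean_accuracy,
            "cv_fold_accuracies": None if cv is None else cv.fold_accuracies,
            "controller": rp.summarize_commands(commands),
            "seed": cfg.seed,
        }
    }
    import json

    paths["report_json"] = outdir / "report.json"
    paths["report_json"].write_text(json.dumps(session_report, indent=2, sort_keys=True))
    md = ["# Session summary", ""]
    s = session_report["session"]
    md.append(f"- windows: {s['n_windows']}, labels: {s['label_counts']}")
    md.append(f"- fatigue fraction: {s['fatigue_fraction']:.3f}")
    if s["cv_mean_accuracy"] is not None:
        md.append(f"- stratified {cfg.cv_folds}-fold CV mean accuracy: {s['cv_mean_accuracy']:.3f}")
    c = s["controller"]
    md.append(
        f"- controller: {c['n_transitions']} transition(s), final state {c['final_state']}, "
        f"final amplitude {c.get('final_amplitude_ma', float('nan')):.2f} mA"
    )
    md.append("")
    paths["report_md"] = outdir / "report.md"
    paths["report_md"].write_text("\n".join(md))
    _log_artifact("report", paths["report_json"])

    return PipelineResult(
        paths=paths,
        session=session,
        features=windows,
        labels=labels,
        model=model,
        cv=cv,
        decisions=np.asarray(decisions, float),
        commands=commands,
        report=session_report,
    )
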