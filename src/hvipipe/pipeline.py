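"""Reproducible pipeline runs: config, simulate / measure / flow / analyze.

Every stochastic step draws from a seed derived deterministically from the
single config seed, so a config file fully reproduces a run. Data go to
files; structured progress messages go to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import preprocess, synthetic, video_io, width
from .exceptions import HviError, ParameterError
from .stats import summarize_study

__all__ = ["RunConfig", "cmd_simulate", "cmd_measure", "cmd_flow", "cmd_analyze"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run (TOML round-trippable)."""

    seed: int | None = None
    out_dir: str = "hvipipe_out"
    n_clips: int = 1
    scene: dict = field(default_factory=lambda: {"blink_frames": [[40, 5]]})
    study: dict = field(default_factory=dict)
    line: list | None = None          # [x0, y0, x1, y1]
    subsample: bool = False
    dim_factor: float = 0.6
    window: int = 31
    segment_len: int = 30
    smooth_sigma: float = 2.0
    max_lag: int = 15
    flow_threshold: float = 0.5

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self) -> str:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            if isinstance(v, str):
                return json.dumps(v)
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            raise TypeError(f"cannot serialize {type(v)}")

        lines = []
        tables = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, dict):
                tables.append((f.name, v))
            else:
                lines.append(f"{f.name} = {fmt(v)}")
        for name, tab in tables:
            lines.append(f"\n[{name}]")
            for k, v in tab.items():
                lines.append(f"{k} = {fmt(v)}")
        return "\n".join(lines) + "\n"

    def validate(self) -> list[str]:
        problems = []
        if self.seed is None:
            problems.append("seed: required (every stochastic step must be seeded)")
        if self.n_clips < 0:
            problems.append("n_clips: must be >= 0")
        if self.window % 2 == 0:
            problems.append("window: must be odd")
        if self.line is not None and len(self.line) != 4:
            problems.append("line: must be [x0, y0, x1, y1]")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ParameterError("invalid config: " + "; ".join(problems))


def _log(msg: str) -> None:
    print(f"[hvipipe] {msg}", file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_line(scene: synthetic.SceneParams) -> width.SamplingLine:
    """Measurement line through the axis point, perpendicular to the vessel."""
    theta = np.deg2rad(scene.axis_angle_deg)
    nx, ny = -np.sin(theta), np.cos(theta)
    cx, cy = scene.axis_point
    half = scene.vessel_width_px / 2.0 + 12.0
    half = min(half,
               *( (lim - c) / abs(d) if d > 0 else (c / abs(d) if d < 0 else np.inf)
                  for c, d, lim in ((cx, nx, scene.image_width_px - 1),
                                    (cy, ny, scene.image_height_px - 1),
                                    (cx, -nx, scene.image_width_px - 1),
                                    (cy, -ny, scene.image_height_px - 1)) ))
    return width.SamplingLine(cx - half * nx, cy - half * ny,
                              cx + half * nx, cy + half * ny)


def cmd_simulate(config: RunConfig) -> Path:
    """Render synthetic vein clips plus a simulated crossover study table.

    Writes ``clip_###.avi`` with JSON ground-truth sidecars, ``study.csv``,
    and a ``manifest.json`` with SHA-256 checksums. Deterministic given the
    config seed.
    """
    config.require_valid()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)
    clip_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                  root_seq.spawn(config.n_clips + 1)]

    entries = []
    for i in range(config.n_clips):
        params = synthetic.SceneParams(**{**config.scene, "seed": clip_seeds[i]})
        avi, sidecar = synthetic.render_and_save(params, out / f"clip_{i:03d}")
        entries.append({"clip": avi.name, "sidecar": sidecar.name,
                        "sha256": _sha256(avi)})
        _log(f"rendered {avi.name}")

    study = synthetic.StudyDesignParams(**{**config.study, "seed": clip_seeds[-1]})
    table, _ = synthetic.render_crossover_study(study)
    study_csv = out / "study.csv"
    table.to_csv(study_csv, index=False)
    entries.append({"study": study_csv.name, "sha256": _sha256(study_csv),
                    "n_subjects": study.n_subjects})

    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"seed": config.seed, "entries": entries},
                                   indent=1, sort_keys=True))
    _log(f"manifest -> {manifest}")
    return manifest


def _prepare_clip(config: RunConfig, clip: video_io.VideoClip):
    if clip.channel_tag == "rgb":
        clip = video_io.extract_green_channel(clip)
    if config.subsample:
        clip = video_io.subsample_alternate_frames(clip)
    blinks = preprocess.detect_blinks(clip, dim_factor=config.dim_factor,
                                      window=config.window)
    segment = preprocess.select_post_blink_segment(clip, blinks,
                                                   segment_len=config.segment_len)
    stabilized, trace = preprocess.stabilize(segment)
    return stabilized, trace, blinks


def _clip_line(config: RunConfig, avi: Path) -> width.SamplingLine:
    if config.line is not None:
        return width.SamplingLine(*config.line)
    sidecar = avi.with_suffix(".json")
    if sidecar.exists():
        scene = synthetic.SceneParams(**json.loads(sidecar.read_text())["scene"])
        return _default_line(scene)
    raise ParameterError(f"no measurement line configured and no sidecar for {avi.name}")


def cmd_measure(config: RunConfig, clips: list[Path] | None = None) -> pd.DataFrame:
    """Width per clip: subsample -> blink/segment -> stabilize -> measure.

    Per-clip failures are logged and flagged in the summary rather than
    aborting the batch. Writes per-frame widths and a one-row-per-clip
    summary CSV to the output directory.
    """
    config.require_valid()
    out = Path(config.out_dir)
    if clips is None:
        clips = sorted(out.glob("clip_*.avi"))
    rows = []
    per_frame = []
    for avi in clips:
        row = {"clip": avi.name, "status": "ok", "mean_width_px": np.nan,
               "sd_width_px": np.nan, "n_unmeasurable": 0,
               "max_shift_px": np.nan}
        try:
            clip = video_io.read_video(avi)
            stabilized, trace, _ = _prepare_clip(config, clip)
            line = _clip_line(config, avi)
            m = width.measure_width_clip(stabilized, line,
                                         n_frames=config.segment_len,
                                         smooth_sigma_px=config.smooth_sigma)
            row.update(mean_width_px=m.mean_width_px, sd_width_px=m.sd_width_px,
                       n_unmeasurable=m.n_unmeasurable,
                       max_shift_px=float(np.abs(trace.shifts).max()))
            for i, wv in enumerate(m.per_frame_widths):
                per_frame.append({"clip": avi.name, "frame": i, "width_px": wv})
        except HviError as exc:
            row["status"] = f"{type(exc).__name__}: {exc}"
            _log(f"{avi.name}: {row['status']}")
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "widths_summary.csv", index=False)
    pd.DataFrame(per_frame).to_csv(out / "widths_per_frame.csv", index=False)
    n_failed = int((summary["status"] != "ok").sum())
    _log(f"measured {len(rows)} clips ({n_failed} failed)")
    return summary


def cmd_flow(config: RunConfig, clips: list[Path] | None = None) -> pd.DataFrame:
    """Decorrelation-lag flow proxy per clip; writes lag maps and a summary."""
    config.require_valid()
    out = Path(config.out_dir)
    if clips is None:
        clips = sorted(out.glob("clip_*.avi"))
    rows = []
    for avi in clips:
        row = {"clip": avi.name, "status": "ok", "median_lag": np.nan,
               "flow_proxy": np.nan, "n_excluded": np.nan}
        try:
            clip = video_io.read_video(avi)
            if clip.channel_tag == "rgb":
                clip = video_io.extract_green_channel(clip)
            sidecar = avi.with_suffix(".json")
            if sidecar.exists():
                scene = synthetic.SceneParams(
                    **json.loads(sidecar.read_text())["scene"])
                roi = _lane_mask(scene)
            else:
                roi = np.ones(clip.frame_shape, dtype=bool)
            est = flow_mod.flow_metric(clip, roi, max_lag=config.max_lag,
                                       threshold=config.flow_threshold)
            row.update(median_lag=est.median_lag, flow_proxy=est.flow_proxy,
                       n_excluded=est.n_excluded)
            _save_lag_map(est.lag_map, out / f"{avi.stem}_lagmap.png")
        except HviError as exc:
            row["status"] = f"{type(exc).__name__}: {exc}"
            _log(f"{avi.name}: {row['status']}")
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "flow_summary.csv", index=False)
    return summary


def _lane_mask(scene: synthetic.SceneParams, half_width: float = 3.0) -> np.ndarray:
    """Pixels within ``half_width`` px of either blood-lane centre."""
    h, w = scene.image_height_px, scene.image_width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(scene.axis_angle_deg)
    r = (-(xx - scene.axis_point[0]) * np.sin(theta)
         + (yy - scene.axis_point[1]) * np.cos(theta))
    return np.abs(np.abs(r) - scene.column_width_px / 2.0) < half_width


def _save_lag_map(lag_map: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(lag_map, cmap="viridis")
    fig.colorbar(im, ax=ax, label="decorrelation lag n* (frames)")
    ax.set_title("per-pixel decorrelation lag")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def cmd_analyze(config: RunConfig, study_csv: str | Path | None = None) -> dict:
    """Crossover analysis of a long-format measurement table.

    Writes the width and IOP summary tables as CSV and the mixed-model fits
    as JSON.
    """
    config.require_valid()
    out = Path(config.out_dir)
    path = Path(study_csv) if study_csv else out / "study.csv"
    table = pd.read_csv(path)
    missing = set(("subject_id", "sequence", "period", "drug", "timepoint",
                   "width_px", "iop_mmHg")) - set(table.columns)
    if missing:
        raise ParameterError(f"{path.name}: missing columns {sorted(missing)}")
    report = summarize_study(table)
    report["width"].to_csv(out / "report_width.csv", index=False)
    report["iop"].to_csv(out / "report_iop.csv", index=False)
    fits = {tp: (None if fit is None else
                 {"drug_effect": fit.drug_effect, "drug_se": fit.drug_se,
                  "drug_p": fit.drug_p, "df": fit.df,
                  "sigma_u2": fit.sigma_u2, "sigma2": fit.sigma2,
                  "converged": fit.converged})
            for tp, fit in report["lmm"].items()}
    (out / "report_lmm.json").write_text(json.dumps(fits, indent=1))
    _log(f"analysis written to {out}")
    return report
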