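"""Synthetic episcleral-vein videos and crossover studies with known truth.

Real recordings of aqueous columns are not publicly available, so every
downstream stage is exercised on rendered scenes: a bright central aqueous
column flanked by two darker blood lanes, advecting speckle texture in the
lanes, blink-induced global dimming, camera jitter, and sensor noise.

The cross-sectional intensity profile is built so that its two local minima
sit exactly ``column_width_px`` apart: each blood lane is a symmetric
parabolic well around its centre, blended into the aqueous core and the
background by cubic Hermite segments with matched slopes. Ground truth is
therefore exact by construction, not fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ParameterError
from .video_io import VideoClip, write_video

__all__ = [
    "SceneParams",
    "GroundTruth",
    "StudyDesignParams",
    "cross_section_profile",
    "render_video",
    "render_and_save",
    "render_crossover_study",
    "BLINK_DIM_FACTOR",
]

#: Multiplicative global dimming applied during a blink interval.
BLINK_DIM_FACTOR = 0.3

# Table-calibrated defaults for the simulated crossover study: baseline
# aqueous-column widths (px) and percent changes from baseline at each
# timepoint, mean and SD, plus intraocular pressures (mmHg).
_BASELINE_WIDTH = {"ripasudil": (63.7, 19.6), "latanoprost": (66.0, 18.9)}
_PCT_CHANGE = {
    "ripasudil": {"2h": (28.8, 16.3), "8h": (7.6, 12.6)},
    "latanoprost": {"2h": (-2.5, 5.7), "8h": (-4.3, 8.1)},
}
_IOP = {
    "ripasudil": {"baseline": (12.8, 2.5), "2h": (10.6, 2.1), "8h": (11.4, 2.2)},
    "latanoprost": {"baseline": (12.6, 1.7), "2h": (12.3, 2.2), "8h": (10.3, 2.0)},
}


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth description of one synthetic vein video.

    The vessel axis is the line through ``axis_point`` at ``axis_angle_deg``
    (degrees, 0 = horizontal). ``column_width_px`` is the distance between
    the two blood-lane intensity minima of the noiseless cross-section —
    the quantity the width analysis is supposed to recover.
    """

    image_height_px: int = 192
    image_width_px: int = 256
    axis_point: tuple[float, float] = (128.0, 96.0)  # (x, y)
    axis_angle_deg: float = 20.0
    vessel_width_px: float = 120.0
    column_width_px: float = 64.0
    flow_speed_px_per_frame: float = 1.0
    background_intensity: float = 0.62
    aqueous_intensity: float = 0.88
    blood_intensity: float = 0.15
    speckle_grain_px: float = 2.0
    speckle_contrast: float = 0.05
    background_texture_contrast: float = 0.08
    background_grain_px: float = 3.0
    noise_sd: float = 0.02
    jitter_sd_px: float = 1.0
    blink_frames: tuple[tuple[int, int], ...] = ()
    fps: float = 60.0
    n_frames: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ParameterError("image dimensions must be positive")
        if not (0.0 < self.column_width_px < self.vessel_width_px
                < min(self.image_height_px, self.image_width_px)):
            raise ParameterError(
                "need 0 < column_width_px < vessel_width_px < min(image dims)")
        ints = (self.background_intensity, self.aqueous_intensity, self.blood_intensity)
        if not all(0.0 <= v <= 1.0 for v in ints):
            raise ParameterError("intensities must lie in [0, 1]")
        if not self.blood_intensity < self.aqueous_intensity:
            raise ParameterError("blood_intensity must be below aqueous_intensity")
        if self.speckle_grain_px <= 0:
            raise ParameterError("speckle_grain_px must be positive")
        if min(self.noise_sd, self.jitter_sd_px, self.speckle_contrast,
               self.background_texture_contrast) < 0:
            raise ParameterError("noise/jitter/texture amplitudes must be >= 0")
        if self.background_grain_px <= 0:
            raise ParameterError("background_grain_px must be positive")
        if self.fps <= 0 or self.n_frames < 1:
            raise ParameterError("fps and n_frames must be positive")
        object.__setattr__(self, "blink_frames",
                           tuple((int(a), int(b)) for a, b in self.blink_frames))
        for start, length in self.blink_frames:
            if length < 1 or start < 0 or start + length > self.n_frames:
                raise ParameterError(
                    f"blink interval ({start}, {length}) outside [0, {self.n_frames})")


@dataclass(frozen=True)
class GroundTruth:
    """What was actually rendered: per-frame jitter, width, speed, blinks."""

    jitter_px: np.ndarray  # (n_frames, 2) applied (dx, dy)
    column_width_px: float
    flow_speed_px_per_frame: float
    blink_frames: frozenset[int]

    def to_json_dict(self) -> dict:
        return {
            "jitter_px": np.asarray(self.jitter_px).tolist(),
            "column_width_px": self.column_width_px,
            "flow_speed_px_per_frame": self.flow_speed_px_per_frame,
            "blink_frames": sorted(self.blink_frames),
        }


def _hermite(t: np.ndarray, p0: float, m0: float, p1: float, m1: float,
             length: float) -> np.ndarray:
    """Cubic Hermite on [0, 1] with endpoint slopes given per unit distance."""
    t2, t3 = t * t, t * t * t
    return ((2 * t3 - 3 * t2 + 1) * p0 + (t3 - 2 * t2 + t) * m0 * length
            + (-2 * t3 + 3 * t2) * p1 + (t3 - t2) * m1 * length)


def _profile_pieces(params: SceneParams):
    c2 = params.column_width_px / 2.0
    l_out = params.vessel_width_px / 2.0 - c2
    # each blood-lane well is exactly even within |d| <= d_m of its centre
    # (parabola of half-width d0, then a shared hermite shoulder), so Gaussian
    # smoothing of the profile cannot displace the minima
    # the cap keeps a resolvable aqueous core: the well may not extend closer
    # than ~3 px (or half the core radius) to the column centre
    d_m = min(0.8 * min(c2, l_out), 7.0, max(0.5 * c2, c2 - 3.0))
    d0 = 0.5 * d_m
    depth = min(params.aqueous_intensity, params.background_intensity) \
        - params.blood_intensity
    k = 0.35 * depth / d0**2
    return c2, l_out, d_m, d0, k, depth


def cross_section_profile(params: SceneParams, r: np.ndarray) -> np.ndarray:
    """Noiseless, speckle-free intensity at signed distance ``r`` from the axis.

    Even in ``r``; global maximum at ``r = 0`` (aqueous core) and local
    minima exactly at ``r = ±column_width_px / 2`` (blood-lane centres).
    """
    r = np.abs(np.asarray(r, dtype=np.float64))
    c2, l_out, d_m, d0, k, depth = _profile_pieces(params)
    d = r - c2  # signed distance from the lane centre (negative toward core)
    bg, aq, bl = (params.background_intensity, params.aqueous_intensity,
                  params.blood_intensity)
    rim0 = bl + k * d0**2          # top of the parabolic well
    r_m = bl + 0.6 * depth         # well value at the matching half-width d_m
    s_m = (r_m - rim0) / (d_m - d0)  # shared shoulder exit slope

    out = np.full(r.shape, bg)
    ad = np.abs(d)
    # continuation segment lengths are capped at 3*rise/slope so the cubic
    # Hermite pieces stay monotone (no spurious extrema); the remainder is a
    # flat plateau at the aqueous-core / background level
    h_in = min(c2 - d_m, 3.0 * (aq - r_m) / s_m)
    h_out = min(l_out - d_m, 3.0 * (bg - r_m) / s_m) if bg > r_m else l_out - d_m
    # aqueous plateau and descent to the inner junction at d = -d_m
    m = d < -d_m
    t = np.clip((r[m] - (c2 - d_m - h_in)) / h_in, 0.0, 1.0)
    out[m] = _hermite(t, aq, 0.0, r_m, -s_m, h_in)
    # even well: parabola (exact minimum at d = 0) plus mirrored shoulders
    m = (ad <= d0) & (d >= -d_m)
    out[m] = bl + k * d[m] ** 2
    m = (ad > d0) & (ad <= d_m) & (d >= -d_m) & (d <= d_m)
    t = (ad[m] - d0) / (d_m - d0)
    out[m] = _hermite(t, rim0, 2 * k * d0, r_m, s_m, d_m - d0)
    # outer junction -> background plateau
    m = (d > d_m) & (d <= d_m + h_out)
    t = (d[m] - d_m) / h_out
    out[m] = _hermite(t, r_m, s_m, bg, 0.0, h_out)
    m = (d > d_m + h_out) & (d <= l_out)
    out[m] = bg
    return out


def _speckle_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                   grain_px: float) -> np.ndarray:
    """Band-limited unit-variance texture (Gaussian-filtered white noise)."""
    raw = rng.standard_normal((n_rows, n_cols))
    f = ndimage.gaussian_filter(raw, sigma=grain_px, mode="wrap")
    return f / f.std()


def render_video(params: SceneParams) -> tuple[VideoClip, GroundTruth]:
    """Render a synthetic vein video; deterministic given ``params.seed``.

    Speckle texture inside the blood lanes translates along the vessel axis
    by ``flow_speed_px_per_frame`` per frame (whole-pixel plus linear
    interpolation). Blinks multiply the whole frame by
    :data:`BLINK_DIM_FACTOR`; jitter is applied as an exact subpixel shift of
    the scene coordinates; sensor noise is additive white Gaussian, clipped
    to [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    h, w, T = params.image_height_px, params.image_width_px, params.n_frames
    theta = np.deg2rad(params.axis_angle_deg)
    ct, st = np.cos(theta), np.sin(theta)
    px0, py0 = params.axis_point

    jitter = (rng.standard_normal((T, 2)) * params.jitter_sd_px
              if params.jitter_sd_px > 0 else np.zeros((T, 2)))

    # axis-aligned coordinates of the jitter-free pixel grid
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    s_base = (xx - px0) * ct + (yy - py0) * st
    r_base = -(xx - px0) * st + (yy - py0) * ct

    # static texture in (s, r) space, long enough to advect for the whole clip
    drift = abs(params.flow_speed_px_per_frame) * T
    jpad = 4.0 * params.jitter_sd_px + 2.0
    s_lo = s_base.min() - jpad - (drift if params.flow_speed_px_per_frame > 0 else 0)
    s_hi = s_base.max() + jpad + (drift if params.flow_speed_px_per_frame < 0 else 0)
    r_lo, r_hi = r_base.min() - jpad, r_base.max() + jpad
    n_r = int(np.ceil(r_hi - r_lo)) + 3
    n_s = int(np.ceil(s_hi - s_lo)) + 3
    field = _speckle_field(rng, n_r, n_s, params.speckle_grain_px)
    # static scleral texture outside the vessel: anchors registration the way
    # conjunctival/scleral detail does in real footage
    bg_field = _speckle_field(rng, n_r, n_s, params.background_grain_px)

    c2, l_out, *_ = _profile_pieces(params)
    # speckle concentrated on the lane centres so the moving-blood texture
    # lives in the dark lanes, not on the shoulders
    lane_sigma = min(0.35 * min(c2, l_out), 4.0)
    blink_set = frozenset(
        f for start, length in params.blink_frames for f in range(start, start + length))

    noise = (rng.standard_normal((T, h, w)) * params.noise_sd
             if params.noise_sd > 0 else None)

    frames = np.empty((T, h, w))
    for t in range(T):
        dx, dy = jitter[t]
        # jitter moves the scene content by (+dx, +dy) on the sensor
        s = s_base - (dx * ct + dy * st)
        r = r_base - (-dx * st + dy * ct)
        frame = cross_section_profile(params, r)
        if params.speckle_contrast > 0:
            d = np.abs(r) - c2
            weight = np.exp(-0.5 * (d / lane_sigma) ** 2)
            coords = np.stack([r - r_lo,
                               s - params.flow_speed_px_per_frame * t - s_lo])
            tex = ndimage.map_coordinates(field, coords, order=1, mode="nearest")
            frame = frame + params.speckle_contrast * weight * tex
        if params.background_texture_contrast > 0:
            # smooth ramp from 0 inside the vessel to 1 on the sclera
            edge = np.clip((np.abs(r) - params.vessel_width_px / 2.0) / 4.0, 0.0, 1.0)
            bg_w = edge * edge * (3.0 - 2.0 * edge)
            tex = ndimage.map_coordinates(bg_field, np.stack([r - r_lo, s - s_lo]),
                                          order=1, mode="nearest")
            frame = frame + params.background_texture_contrast * bg_w * tex
        if t in blink_set:
            frame = frame * BLINK_DIM_FACTOR
        if noise is not None:
            frame = frame + noise[t]
        frames[t] = np.clip(frame, 0.0, 1.0)

    clip = VideoClip(frames, fps=params.fps, channel_tag="grayscale")
    truth = GroundTruth(jitter_px=jitter, column_width_px=params.column_width_px,
                        flow_speed_px_per_frame=params.flow_speed_px_per_frame,
                        blink_frames=blink_set)
    return clip, truth


def render_and_save(params: SceneParams, stem: str | Path) -> tuple[Path, Path]:
    """Render and write ``<stem>.avi`` plus a ``<stem>.json`` truth sidecar."""
    clip, truth = render_video(params)
    stem = Path(stem)
    avi = stem.with_suffix(".avi")
    sidecar = stem.with_suffix(".json")
    write_video(clip, avi)
    payload = {"scene": asdict(params), "ground_truth": truth.to_json_dict()}
    sidecar.write_text(json.dumps(payload, indent=1))
    return avi, sidecar


@dataclass(frozen=True)
class StudyDesignParams:
    """Generative model for a simulated two-sequence crossover study.

    Per subject and drug, a baseline width is drawn from the drug's baseline
    normal model and post-instillation widths are
    ``baseline * (1 + pct/100)`` with ``pct`` drawn from the per-drug,
    per-timepoint percent-change model. SD = 0 degenerates to a point mass;
    negative SDs are rejected.
    """

    n_subjects: int = 16
    baseline_width: dict = field(default_factory=lambda: dict(_BASELINE_WIDTH))
    pct_change: dict = field(default_factory=lambda: {
        d: dict(v) for d, v in _PCT_CHANGE.items()})
    iop: dict = field(default_factory=lambda: {d: dict(v) for d, v in _IOP.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ParameterError("n_subjects must be an even integer >= 2")
        for table in (self.baseline_width, *self.pct_change.values(),
                      *self.iop.values()):
            for mean_sd in table.values():
                if mean_sd[1] < 0:
                    raise ParameterError(f"negative SD in {mean_sd}")


SEQUENCES = ("ripasudil-latanoprost", "latanoprost-ripasudil")
TIMEPOINTS = ("baseline", "2h", "8h")


def render_crossover_study(
    study: StudyDesignParams,
    seed: int | None = None,
    video_dir: str | Path | None = None,
    scene_template: SceneParams | None = None,
) -> tuple[pd.DataFrame, list[Path]]:
    """Simulate a crossover study as a long-format measurement table.

    Subjects are randomized 1:1 to the two sequences. Returns one row per
    subject x period x timepoint with columns ``subject_id, sequence,
    period, drug, timepoint, width_px, iop_mmHg``. If ``video_dir`` is
    given, one vein video per observation is rendered with the observed
    width as its true column width (sidecar JSON included) and the paths
    are returned.
    """
    rng = np.random.default_rng(study.seed if seed is None else seed)
    n = study.n_subjects
    order = rng.permutation(n)
    seq_of = {int(s): SEQUENCES[0] if i < n // 2 else SEQUENCES[1]
              for i, s in enumerate(order)}

    rows = []
    videos: list[Path] = []
    for subject in range(n):
        sequence = seq_of[subject]
        drugs = sequence.split("-")
        for period, drug in enumerate(drugs, start=1):
            mu_b, sd_b = study.baseline_width[drug]
            baseline = rng.normal(mu_b, sd_b)
            widths = {"baseline": baseline}
            for tp in ("2h", "8h"):
                mu, sd = study.pct_change[drug][tp]
                widths[tp] = baseline * (1.0 + rng.normal(mu, sd) / 100.0)
            for tp in TIMEPOINTS:
                mu_i, sd_i = study.iop[drug][tp]
                rows.append({
                    "subject_id": f"S{subject:02d}",
                    "sequence": sequence,
                    "period": period,
                    "drug": drug,
                    "timepoint": tp,
                    "width_px": widths[tp],
                    "iop_mmHg": rng.normal(mu_i, sd_i),
                })
    table = pd.DataFrame(rows)

    if video_dir is not None:
        video_dir = Path(video_dir)
        video_dir.mkdir(parents=True, exist_ok=True)
        template = scene_template or SceneParams()
        for i, row in table.iterrows():
            width = float(np.clip(row.width_px, 6.0, template.vessel_width_px - 8.0))
            params = SceneParams(**{**asdict(template),
                                    "column_width_px": width,
                                    "seed": int(rng.integers(2**31))})
            stem = video_dir / (f"{row.subject_id}_p{row.period}_{row.drug}"
                                f"_{row.timepoint}")
            avi, _ = render_and_save(params, stem)
            videos.append(avi)
    return table, videos
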