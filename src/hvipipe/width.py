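"""Aqueous-column width from cross-sectional intensity profiles.

Under green-filter illumination the blood lanes flanking the clear aqueous
column absorb strongly, so a line placed across the vein yields a profile
with a bright central maximum and two dark local minima. The column width is
defined as the distance between those two minima, measured per frame over a
30-frame slice and averaged; two observers' values are averaged in turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .exceptions import MeasurementFailure, ParameterError, UnmeasurableProfileError
from .video_io import VideoClip

__all__ = [
    "SamplingLine",
    "IntensityProfile",
    "WidthMeasurement",
    "extract_profile",
    "measure_width",
    "measure_width_clip",
    "average_observers",
    "percent_change",
]


@dataclass(frozen=True)
class SamplingLine:
    """A measurement line in continuous pixel coordinates (0-based, pixel
    centers at integers), from (x0, y0) to (x1, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if (self.x0, self.y0) == (self.x1, self.y1):
            raise ParameterError("line endpoints must be distinct")

    @property
    def length(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))


@dataclass(frozen=True)
class IntensityProfile:
    """Intensities sampled at uniform spacing along a line.

    ``positions`` are distances along the line in px, strictly increasing
    with constant spacing; endpoints of the line are included.
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        val = np.asarray(self.intensities, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", val)
        if pos.shape != val.shape or pos.ndim != 1 or pos.size < 2:
            raise ParameterError("positions/intensities must be matching 1-D arrays")
        steps = np.diff(pos)
        if not (steps > 0).all() or not np.allclose(steps, steps[0]):
            raise ParameterError("positions must be strictly increasing and uniform")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class WidthMeasurement:
    """Per-frame widths for one clip/observer with their mean and SD."""

    per_frame_widths: np.ndarray
    mean_width_px: float
    sd_width_px: float
    observer_label: str = ""
    n_unmeasurable: int = 0


def extract_profile(frame: np.ndarray, line: SamplingLine) -> IntensityProfile:
    """Sample a frame along a line by bilinear interpolation.

    Samples are placed at uniform spacing ``length / ceil(length)`` (≤ 1 px),
    endpoints inclusive, so an axis-aligned line on integer coordinates
    reproduces the raw pixel values exactly.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    for x, y in ((line.x0, line.y0), (line.x1, line.y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ParameterError(f"line endpoint ({x}, {y}) outside frame {frame.shape}")
    n_steps = max(1, int(np.ceil(line.length)))
    t = np.linspace(0.0, 1.0, n_steps + 1)
    xs = line.x0 + t * (line.x1 - line.x0)
    ys = line.y0 + t * (line.y1 - line.y0)
    vals = ndimage.map_coordinates(frame, np.stack([ys, xs]), order=1, mode="nearest")
    return IntensityProfile(positions=t * line.length, intensities=vals)


def _core_maximum(vals: np.ndarray) -> int:
    """Index of the aqueous-core maximum.

    The most prominent interior local maximum is used rather than the raw
    global maximum: on a noisy profile the brightest sample can sit on the
    background plateau, whereas the core peak — walled in by the two dark
    blood lanes — always dominates in prominence. Falls back to the global
    maximum when no interior peak exists (e.g. a monotone ramp).
    """
    peaks, props = signal.find_peaks(vals, prominence=0.0)
    if peaks.size == 0:
        return int(np.argmax(vals))
    return int(peaks[np.argmax(props["prominences"])])


def _parabolic_offset(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom <= 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))


def measure_width(profile: IntensityProfile, smooth_sigma_px: float = 2.0) -> float:
    """Distance (px) between the two blood-lane minima flanking the core.

    The profile is Gaussian-smoothed (sigma in px), the most prominent
    interior maximum is taken as the aqueous core, the deepest local minimum
    on each side is the lane centre, and each minimum is refined to subpixel
    by a parabolic fit over its 3-point neighbourhood. Raises
    :class:`UnmeasurableProfileError` when the maximum sits on the profile
    edge or either side lacks a local minimum.
    """
    vals = profile.intensities
    spacing = profile.spacing
    if smooth_sigma_px > 0:
        vals = ndimage.gaussian_filter1d(vals, smooth_sigma_px / spacing,
                                         mode="nearest")
    n = vals.size
    i_max = _core_maximum(vals)
    if i_max in (0, n - 1):
        raise UnmeasurableProfileError("profile maximum on the edge; no central core")

    interior = (vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:])
    candidates = np.flatnonzero(interior) + 1
    # strict minima only: collapse flat runs to their centre sample
    strict = []
    run_start = None
    for i in candidates:
        if run_start is None:
            run_start = prev = i
        elif i == prev + 1 and vals[i] == vals[prev]:
            prev = i
        else:
            strict.append((run_start + prev) // 2)
            run_start = prev = i
    if run_start is not None:
        strict.append((run_start + prev) // 2)
    mins = np.array(strict, dtype=int)

    left = mins[mins < i_max]
    right = mins[mins > i_max]
    if left.size == 0 or right.size == 0:
        raise UnmeasurableProfileError(
            "need a local minimum on each side of the profile maximum")

    def refine(side: np.ndarray) -> float:
        depth_order = np.argsort(vals[side], kind="stable")
        deepest = vals[side][depth_order[0]]
        # tie between equally deep minima broken toward the central maximum
        tied = side[np.isclose(vals[side], deepest)]
        i = tied[np.argmin(np.abs(tied - i_max))]
        if 0 < i < n - 1:
            i = i + _parabolic_offset(vals[i - 1], vals[i], vals[i + 1])
        return float(i)

    return (refine(right) - refine(left)) * spacing


def measure_width_clip(clip: VideoClip, line: SamplingLine, n_frames: int = 30,
                       smooth_sigma_px: float = 2.0,
                       observer_label: str = "") -> WidthMeasurement:
    """Per-frame widths over the first ``n_frames`` frames of a clip.

    Frames whose profile is unmeasurable are excluded and counted; if more
    than half of the frames are unmeasurable the whole measurement fails.
    """
    if clip.channel_tag == "rgb":
        raise ParameterError("measure on a single-channel clip "
                             "(extract_green_channel first)")
    if clip.n_frames < n_frames:
        raise ParameterError(
            f"clip has {clip.n_frames} frames; {n_frames} required")
    widths = []
    n_bad = 0
    for frame in clip.frames[:n_frames]:
        try:
            widths.append(measure_width(extract_profile(frame, line),
                                        smooth_sigma_px=smooth_sigma_px))
        except UnmeasurableProfileError:
            n_bad += 1
    if n_bad > n_frames // 2:
        raise MeasurementFailure(
            f"{n_bad}/{n_frames} frames unmeasurable")
    arr = np.asarray(widths)
    return WidthMeasurement(
        per_frame_widths=arr,
        mean_width_px=float(arr.mean()),
        sd_width_px=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        observer_label=observer_label,
        n_unmeasurable=n_bad,
    )


def average_observers(m1: WidthMeasurement, m2: WidthMeasurement) -> float:
    """Arithmetic mean of two observers' mean widths."""
    return 0.5 * (m1.mean_width_px + m2.mean_width_px)


def percent_change(baseline_px: float, value_px: float) -> float:
    """Percent change from baseline: ``100 * (value - baseline) / baseline``."""
    if baseline_px <= 0:
        raise ParameterError("baseline width must be positive")
    return 100.0 * (value_px - baseline_px) / baseline_px
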