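"""Blink detection, post-blink segment selection, and stabilization.

Aqueous flow in the episcleral vein slows between blinks, so measurement
segments are anchored immediately after a blink. Camera shake is removed by
translation-only registration (rotation in slit-lamp footage is negligible,
and the width measurement is translation-invariant anyway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .exceptions import NoSegmentError, ParameterError
from .video_io import VideoClip

__all__ = [
    "BlinkEvent",
    "ShiftTrace",
    "detect_blinks",
    "select_post_blink_segment",
    "estimate_shift",
    "stabilize",
]


@dataclass(frozen=True)
class BlinkEvent:
    """A maximal run of blink frames, half-open ``[start_frame, end_frame)``."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ParameterError("blink event must satisfy start < end")

    def __contains__(self, frame: int) -> bool:
        return self.start_frame <= frame < self.end_frame


@dataclass(frozen=True)
class ShiftTrace:
    """Estimated per-frame (dx, dy) translation relative to a reference frame.

    ``shifts[t]`` is how far frame ``t``'s content is displaced from the
    reference frame's; the shift at the reference frame is (0, 0).
    """

    shifts: np.ndarray  # (T, 2)
    reference_index: int


def detect_blinks(clip: VideoClip, dim_factor: float = 0.6,
                  window: int = 31) -> list[BlinkEvent]:
    """Find blink events as global-intensity dips.

    A frame is a blink frame when its mean intensity falls below
    ``dim_factor`` times the rolling median of the mean-intensity trace
    (window length ``window``, odd). Self-normalizing: an all-dark but
    steady clip yields no blinks.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError("window must be an odd integer >= 3")
    if clip.n_frames < window:
        raise ParameterError(f"clip shorter ({clip.n_frames}) than window ({window})")
    trace = clip.frames.reshape(clip.n_frames, -1).mean(axis=1)
    baseline = ndimage.median_filter(trace, size=window, mode="nearest")
    is_blink = trace < dim_factor * baseline

    events = []
    start = None
    for i, b in enumerate(is_blink):
        if b and start is None:
            start = i
        elif not b and start is not None:
            events.append(BlinkEvent(start, i))
            start = None
    if start is not None:
        events.append(BlinkEvent(start, clip.n_frames))
    return events


def select_post_blink_segment(clip: VideoClip, blinks: list[BlinkEvent],
                              segment_len: int = 30) -> VideoClip:
    """The ``segment_len`` frames starting right after the earliest blink
    that leaves room for a full segment."""
    for blink in sorted(blinks, key=lambda b: b.start_frame):
        start = blink.end_frame
        if start + segment_len <= clip.n_frames:
            return VideoClip(clip.frames[start:start + segment_len],
                             fps=clip.fps, channel_tag=clip.channel_tag)
    raise NoSegmentError(
        f"no blink with {segment_len} frames after it (blinks: {len(blinks)})")


def _window2d(shape: tuple[int, int]) -> np.ndarray:
    # edge taper only (Tukey): suppresses FFT wraparound without
    # down-weighting static scene detail away from the frame centre
    wy = signal.windows.tukey(shape[0], alpha=0.25)
    wx = signal.windows.tukey(shape[1], alpha=0.25)
    return np.outer(wy, wx)


def _parabolic(y_m1: float, y_0: float, y_p1: float) -> float:
    """Vertex offset in (-0.5, 0.5) of a parabola through three samples
    centred on a local maximum."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom >= 0:  # not a proper peak
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))


def estimate_shift(reference: np.ndarray, frame: np.ndarray,
                   lowpass_sigma_px: float = 1.0) -> tuple[float, float]:
    """Estimate the (dx, dy) translation of ``frame`` relative to ``reference``
    by phase correlation with subpixel quadratic refinement of the peak.

    Both images are low-pass filtered (``lowpass_sigma_px``) first; this
    suppresses the sensor-noise part of the spectrum that whitening would
    otherwise amplify. Returns (0, 0) with a warning when either image is
    constant.
    """
    ref = np.asarray(reference, dtype=np.float64)
    img = np.asarray(frame, dtype=np.float64)
    if ref.shape != img.shape:
        raise ParameterError("frames must share a shape")
    if np.ptp(ref) == 0 or np.ptp(img) == 0:
        warnings.warn("constant frame: shift undefined, returning (0, 0)",
                      stacklevel=2)
        return 0.0, 0.0
    if lowpass_sigma_px > 0:
        ref = ndimage.gaussian_filter(ref, lowpass_sigma_px)
        img = ndimage.gaussian_filter(img, lowpass_sigma_px)
    win = _window2d(ref.shape)
    f_ref = np.fft.rfft2((ref - ref.mean()) * win)
    f_img = np.fft.rfft2((img - img.mean()) * win)
    cross = f_img * np.conj(f_ref)
    mag = np.abs(cross)
    # partially whitened cross-power spectrum: full phase normalization
    # amplifies spectral bands where the scene has no energy, so the
    # magnitude is floored at a fraction of its mean
    cross /= mag + 0.05 * mag.mean() + 1e-300
    corr = np.fft.irfft2(cross, s=ref.shape)

    peak = np.unravel_index(np.argmax(corr), corr.shape)
    h, w = corr.shape
    iy, ix = int(peak[0]), int(peak[1])
    # quadratic fit of the (wrapped) correlation peak, one axis at a time
    dy = iy + _parabolic(corr[(iy - 1) % h, ix], corr[iy, ix], corr[(iy + 1) % h, ix])
    dx = ix + _parabolic(corr[iy, (ix - 1) % w], corr[iy, ix], corr[iy, (ix + 1) % w])
    if dy > h / 2:
        dy -= h
    if dx > w / 2:
        dx -= w
    return float(dx), float(dy)


def stabilize(clip: VideoClip, reference_index: int = 0) -> tuple[VideoClip, ShiftTrace]:
    """Remove camera shake by translation-only registration.

    Each frame's shift against the reference frame is estimated by phase
    correlation and removed (linear interpolation, borders filled by edge
    replication). Returns the stabilized clip and the estimated
    :class:`ShiftTrace`.
    """
    if clip.n_frames < 2:
        raise ParameterError("need at least 2 frames to stabilize")
    if not 0 <= reference_index < clip.n_frames:
        raise ParameterError("reference_index out of range")
    ref = clip.frames[reference_index]
    shifts = np.zeros((clip.n_frames, 2))
    out = np.empty_like(clip.frames)
    for t in range(clip.n_frames):
        if t == reference_index:
            out[t] = clip.frames[t]
            continue
        dx, dy = estimate_shift(ref, clip.frames[t])
        shifts[t] = (dx, dy)
        if dx == 0.0 and dy == 0.0:
            out[t] = clip.frames[t]
        else:
            out[t] = ndimage.shift(clip.frames[t], (-dy, -dx), order=1,
                                   mode="nearest")
    stabilized = VideoClip(out, fps=clip.fps, channel_tag=clip.channel_tag)
    return stabilized, ShiftTrace(shifts=shifts, reference_index=reference_index)
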