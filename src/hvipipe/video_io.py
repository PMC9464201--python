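"""Video clips and frame-rate handling.

Clips are stored as float stacks in [0, 1] — one internal intensity scale
for all downstream math. The frame-rate convention mirrors the acquisition
protocol the pipeline targets: 60 fps capture analysed at 30 fps by keeping
every other frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._avi import read_avi, write_avi
from .exceptions import ParameterError, VideoIOError

__all__ = [
    "VideoClip",
    "read_video",
    "write_video",
    "extract_green_channel",
    "subsample_alternate_frames",
]


@dataclass(frozen=True)
class VideoClip:
    """An ordered stack of frames with rate and channel metadata.

    ``frames`` is ``(T, H, W)`` for single-channel clips (channel_tag
    ``"grayscale"`` or ``"green-extracted"``) or ``(T, H, W, 3)`` for
    ``"rgb"``; values are floats in [0, 1].
    """

    frames: np.ndarray
    fps: float
    channel_tag: str = "grayscale"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=np.float64)
        object.__setattr__(self, "frames", f)
        if f.ndim not in (3, 4) or f.shape[0] < 1:
            raise ParameterError(f"frames must be (T,H,W[,3]); got {f.shape}")
        if f.ndim == 4 and f.shape[-1] != 3:
            raise ParameterError("multi-channel clips must have 3 channels")
        if (f.ndim == 4) != (self.channel_tag == "rgb"):
            raise ParameterError(
                f"channel_tag {self.channel_tag!r} inconsistent with shape {f.shape}")
        if not self.fps > 0:
            raise ParameterError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    def __len__(self) -> int:
        return self.n_frames


def read_video(path: str | Path) -> VideoClip:
    """Read an AVI file into a clip with intensities normalized to [0, 1].

    RGB content is kept as ``channel_tag="rgb"``; files whose three planes
    are identical are collapsed to grayscale. Frame rate comes from the
    container header.
    """
    path = Path(path)
    if not path.exists():
        raise VideoIOError(f"{path}: no such file")
    frames_u8, fps = read_avi(path)
    frames = frames_u8.astype(np.float64) / 255.0
    if np.array_equal(frames_u8[..., 0], frames_u8[..., 1]) and np.array_equal(
            frames_u8[..., 0], frames_u8[..., 2]):
        return VideoClip(frames[..., 0], fps=fps, channel_tag="grayscale")
    return VideoClip(frames, fps=fps, channel_tag="rgb")


def write_video(clip: VideoClip, path: str | Path) -> None:
    """Write a clip as an uncompressed AVI (8-bit quantization).

    Intensities on the 1/255 grid round-trip bit-exactly through
    ``write_video`` / ``read_video``.
    """
    u8 = np.round(np.clip(clip.frames, 0.0, 1.0) * 255.0).astype(np.uint8)
    write_avi(path, u8, clip.fps)


def extract_green_channel(clip: VideoClip) -> VideoClip:
    """Keep the green plane of an RGB clip.

    The imaging protocol uses a 505–575 nm green filter under which
    hemoglobin absorbs strongly, so the green plane carries the blood/aqueous
    contrast. On an already single-channel clip this is a no-op with a
    warning.
    """
    if clip.channel_tag != "rgb":
        warnings.warn("clip is already single-channel; extract_green_channel is a no-op",
                      stacklevel=2)
        return clip
    return VideoClip(clip.frames[..., 1], fps=clip.fps, channel_tag="green-extracted")


def subsample_alternate_frames(clip: VideoClip) -> VideoClip:
    """Keep every other frame (even 0-based indices) and halve the fps.

    This realizes 60 fps capture analysed at 30 fps. Works on any clip; a
    warning is emitted when the input is not nominally 60 fps. ``ceil(n/2)``
    frames are kept.
    """
    if not np.isclose(clip.fps, 60.0, atol=1.0):
        warnings.warn(f"subsampling a {clip.fps:g} fps clip (expected ~60 fps)",
                      stacklevel=2)
    return replace(clip, frames=clip.frames[::2], fps=clip.fps / 2.0)
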