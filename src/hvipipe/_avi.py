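"""Minimal uncompressed AVI (RIFF) reader/writer.

Frames are stored as uncompressed 24-bit bottom-up DIB ('00db' chunks,
biCompression = 0), the plainest AVI flavour there is. Because no codec is
involved, 8-bit pixel data round-trips bit-exactly, which is the contract
the rest of the pipeline relies on.

Only what the pipeline needs is implemented: a single video stream, constant
frame rate, 24-bit BGR frames. The reader tolerates '00dc' chunk ids and an
optional 'idx1' index (both written by common tools).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .exceptions import VideoIOError

_AVIH = struct.Struct("<14I")
_STRH = struct.Struct("<4s4sIHHIIIIIIIIhhhh")
_BMIH = struct.Struct("<IiiHHIIiiII")


def _pad_width(w: int) -> int:
    # DIB rows are padded to 4-byte boundaries
    return (w * 3 + 3) & ~3


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write a uint8 frame stack as an uncompressed AVI.

    Parameters
    ----------
    frames
        ``(T, H, W)`` grayscale or ``(T, H, W, 3)`` RGB uint8 array.
    fps
        Frame rate; stored as the rational ``round(fps * 1000) / 1000``.
    """
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        raise VideoIOError("write_avi expects uint8 frames")
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.shape[0] < 1:
        raise VideoIOError(f"bad frame stack shape {frames.shape}")
    n, h, w, _ = frames.shape
    row_bytes = _pad_width(w)
    frame_bytes = row_bytes * h

    rate = max(1, round(float(fps) * 1000))
    scale = 1000
    usec = round(1e6 * scale / rate)

    avih = _chunk(
        b"avih",
        _AVIH.pack(usec, frame_bytes * rate // scale, 0, 0x10, n, 0, 1,
                   frame_bytes, w, h, 0, 0, 0, 0),
    )
    strh = _chunk(
        b"strh",
        _STRH.pack(b"vids", b"DIB ", 0, 0, 0, 0, scale, rate, 0, n,
                   frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h),
    )
    strf = _chunk(b"strf", _BMIH.pack(40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0))
    strl = _chunk(b"LIST", b"strl" + strh + strf)
    hdrl = _chunk(b"LIST", b"hdrl" + avih + strl)

    # BGR, bottom-up, padded rows
    pad = np.zeros((h, row_bytes - w * 3), dtype=np.uint8)
    movi_payload = b"movi"
    idx_entries = []
    offset = 4  # relative to start of 'movi' fourcc
    for frame in frames:
        bgr = frame[::-1, :, ::-1]
        raw = np.concatenate([bgr.reshape(h, -1), pad], axis=1).tobytes()
        movi_payload += _chunk(b"00db", raw)
        idx_entries.append(struct.pack("<4sII I", b"00db", 0x10, offset, len(raw)))
        offset += 8 + len(raw) + (len(raw) % 2)
    movi = _chunk(b"LIST", movi_payload)
    idx1 = _chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI written by :func:`write_avi`.

    Returns ``(frames, fps)`` with frames as a ``(T, H, W, 3)`` uint8 RGB
    stack. Raises :class:`VideoIOError` on anything that is not a decodable
    uncompressed AVI.
    """
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise VideoIOError(f"{path}: not an AVI (RIFF) file")

    fps = None
    dims = None
    raw_frames: list[bytes] = []

    def walk(buf: bytes) -> None:
        nonlocal fps, dims
        pos = 0
        while pos + 8 <= len(buf):
            fourcc = buf[pos:pos + 4]
            (size,) = struct.unpack_from("<I", buf, pos + 4)
            payload = buf[pos + 8:pos + 8 + size]
            if fourcc == b"LIST":
                walk(payload[4:])
            elif fourcc == b"strh" and len(payload) >= _STRH.size:
                f = _STRH.unpack_from(payload)
                if f[0] == b"vids" and f[7] > 0:
                    fps = f[7] / max(f[6], 1)
            elif fourcc == b"strf" and len(payload) >= _BMIH.size:
                b_ = _BMIH.unpack_from(payload)
                if b_[4] != 24 or b_[5] != 0:
                    raise VideoIOError(
                        f"unsupported AVI pixel format (bits={b_[4]}, "
                        f"compression={b_[5]}); only uncompressed 24-bit DIB is supported")
                dims = (b_[1], abs(b_[2]))
            elif fourcc in (b"00db", b"00dc"):
                raw_frames.append(payload)
            pos += 8 + size + (size % 2)

    walk(data[12:])
    if not raw_frames or dims is None:
        raise VideoIOError(f"{path}: no decodable video frames found")
    w, h = dims
    row_bytes = _pad_width(w)
    frames = np.empty((len(raw_frames), h, w, 3), dtype=np.uint8)
    for i, raw in enumerate(raw_frames):
        if len(raw) < row_bytes * h:
            raise VideoIOError(f"{path}: truncated frame {i}")
        arr = np.frombuffer(raw, dtype=np.uint8, count=row_bytes * h)
        arr = arr.reshape(h, row_bytes)[:, : w * 3].reshape(h, w, 3)
        frames[i] = arr[::-1, :, ::-1]
    return frames, float(fps if fps else 30.0)
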