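"""Video I/O: grayscale frame streams, uncompressed AVI, and TIFF stacks.

The cage cameras this pipeline targets record plain AVI files (the reference
hardware streams 1920x1080 AVI); for portable, dependency-free round-trips the
package reads and writes the classic uncompressed flavour directly: RIFF/AVI
with 8-bit BI_RGB DIB frames and a grayscale palette, which any mainstream
player opens. Multi-page TIFF stacks are supported through tifffile, and other
containers are attempted through imageio when a suitable backend is present.

Frames are 2-D uint8 grayscale grids. RGB input is collapsed with the standard
luma weighting (infrared night-vision footage is effectively single-channel).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np

__all__ = ["FrameStream", "read_video", "write_avi", "write_tiff", "VideoDecodeError", "to_grayscale"]

#: Rec.601 luma weights for RGB -> grayscale collapse.
_LUMA = np.array([0.299, 0.587, 0.114])


class VideoDecodeError(RuntimeError):
    """Raised when a video file cannot be decoded."""


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an (H, W) or (H, W, 3/4) frame to 2-D uint8 via luma weighting."""
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return (arr[..., :3].astype(np.float64) @ _LUMA).round().clip(0, 255).astype(np.uint8)
    raise ValueError(f"cannot interpret frame of shape {arr.shape} as grayscale")


@dataclass
class FrameStream:
    """An ordered stream of 2-D grayscale frames with acquisition metadata.

    ``frames`` may be an in-memory ``(T, H, W)`` array or a zero-argument
    callable returning a fresh iterator of frames — the lazy form lets
    hour-scale renders and file readers stay out of memory while remaining
    re-iterable and byte-reproducible.
    """

    frames: np.ndarray | Callable[[], Iterator[np.ndarray]]
    fps: float
    width: int
    height: int
    n_frames: int
    start_clock: str = "08:00"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"frame dims must be positive, got {self.width}x{self.height}")
        if self.n_frames < 1:
            raise ValueError("a FrameStream needs at least one frame")

    @classmethod
    def from_array(
        cls, frames: np.ndarray, fps: float, start_clock: str = "08:00"
    ) -> "FrameStream":
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError(f"expected (T, H, W) frames, got shape {frames.shape}")
        t, h, w = frames.shape
        return cls(
            frames=frames.astype(np.uint8, copy=False),
            fps=fps,
            width=w,
            height=h,
            n_frames=t,
            start_clock=start_clock,
        )

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def iter_frames(self) -> Iterator[np.ndarray]:
        source = self.frames
        if callable(source):
            it = source()
        else:
            it = iter(source)
        for frame in it:
            g = to_grayscale(frame)
            if g.shape != (self.height, self.width):
                raise ValueError(
                    f"frame shape {g.shape} does not match stream "
                    f"({self.height}, {self.width})"
                )
            yield g

    def load(self) -> np.ndarray:
        """Materialize the whole stream as a (T, H, W) uint8 array."""
        return np.stack(list(self.iter_frames()))


# ---------------------------------------------------------------------------
# Uncompressed 8-bit AVI (RIFF, BI_RGB DIB frames, grayscale palette)
# ---------------------------------------------------------------------------

def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def write_avi(stream: FrameStream, path: str | Path) -> None:
    """Write a FrameStream as an uncompressed 8-bit grayscale AVI file."""
    w, h, n = stream.width, stream.height, stream.n_frames
    fps = stream.fps
    stride = (w + 3) & ~3  # rows padded to 4-byte boundaries
    frame_bytes = stride * h

    rate = int(round(fps * 1000))
    scale = 1000
    usec_per_frame = int(round(1e6 / fps))

    avih = _chunk(
        b"avih",
        struct.pack(
            "<14I",
            usec_per_frame,      # dwMicroSecPerFrame
            frame_bytes * int(np.ceil(fps)),  # dwMaxBytesPerSec (advisory)
            0,                   # dwPaddingGranularity
            0x10,                # dwFlags: AVIF_HASINDEX
            n,                   # dwTotalFrames
            0,                   # dwInitialFrames
            1,                   # dwStreams
            frame_bytes,         # dwSuggestedBufferSize
            w, h, 0, 0, 0, 0,
        ),
    )
    strh = _chunk(
        b"strh",
        b"vids" + b"DIB "
        + struct.pack("<10I4h", 0, 0, 0, scale, rate, 0, n, frame_bytes, 0, 0, 0, 0, w, h),
    )
    palette = b"".join(struct.pack("<4B", i, i, i, 0) for i in range(256))
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    strf = _chunk(b"strf", bmih + palette)
    hdrl = _list(b"hdrl", avih + _list(b"strl", strh + strf))

    movi_payload = bytearray(b"movi")
    index = bytearray()
    offset = 4  # offsets inside movi LIST, counted from the fourcc
    count = 0
    for frame in stream.iter_frames():
        if frame.shape != (h, w):
            raise ValueError(f"frame shape {frame.shape} does not match stream header")
        rows = np.zeros((h, stride), dtype=np.uint8)
        rows[:, :w] = frame[::-1]  # DIBs are bottom-up
        data = rows.tobytes()
        movi_payload += _chunk(b"00db", data)
        index += b"00db" + struct.pack("<3I", 0x10, offset, len(data))
        offset += 8 + len(data) + (len(data) % 2)
        count += 1
    if count != n:
        raise ValueError(f"stream yielded {count} frames but declares n_frames={n}")

    movi = _chunk(b"LIST", bytes(movi_payload))
    idx1 = _chunk(b"idx1", bytes(index))
    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_riff_chunks(buf: bytes, start: int, end: int) -> Iterator[tuple[bytes, int, int]]:
    """Yield (fourcc, payload_start, payload_size) for chunks in buf[start:end]."""
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def _read_avi(path: Path, fps_override: float | None) -> FrameStream:
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise VideoDecodeError(f"{path}: not a RIFF/AVI file")

    width = height = n_frames = 0
    fps = 0.0
    bit_count = None
    compression = None
    movi_span: tuple[int, int] | None = None

    def walk(start: int, end: int) -> None:
        nonlocal width, height, n_frames, fps, bit_count, compression, movi_span
        for fourcc, p, size in _iter_riff_chunks(buf, start, end):
            if fourcc == b"LIST":
                kind = buf[p : p + 4]
                if kind == b"movi":
                    movi_span = (p + 4, p + size)
                else:
                    walk(p + 4, p + size)
            elif fourcc == b"avih":
                vals = struct.unpack_from("<14I", buf, p)
                if vals[0] > 0:
                    fps = 1e6 / vals[0]
                n_frames = vals[4]
                width, height = vals[8], vals[9]
            elif fourcc == b"strh" and buf[p : p + 4] == b"vids":
                scale, rate = struct.unpack_from("<2I", buf, p + 20)
                if scale > 0 and rate > 0:
                    fps = rate / scale
            elif fourcc == b"strf":
                (_, bw, bh, _, bc, comp) = struct.unpack_from("<Iii2HI", buf, p)
                bit_count, compression = bc, comp
                width = width or abs(bw)
                height = height or abs(bh)

    walk(12, len(buf))
    if movi_span is None or width <= 0 or height <= 0:
        raise VideoDecodeError(f"{path}: malformed AVI (no movi list or frame geometry)")
    if compression not in (0, None) or bit_count not in (8, None):
        raise VideoDecodeError(
            f"{path}: only uncompressed 8-bit AVI is supported "
            f"(biCompression={compression}, biBitCount={bit_count}); "
            "re-encode to uncompressed grayscale or convert to a TIFF stack"
        )
    if fps_override is not None:
        fps = fps_override
    if fps <= 0:
        raise VideoDecodeError(
            f"{path}: container reports no frame rate; pass fps explicitly "
            "(fps_override / --fps-override)"
        )

    stride = (width + 3) & ~3
    frame_offsets = [
        (p, size)
        for fourcc, p, size in _iter_riff_chunks(buf, *movi_span)
        if fourcc in (b"00db", b"00dc") and size > 0
    ]
    if not frame_offsets:
        raise VideoDecodeError(f"{path}: AVI contains no frames")

    def gen() -> Iterator[np.ndarray]:
        for p, size in frame_offsets:
            if size < stride * height:
                raise VideoDecodeError(f"{path}: truncated frame chunk at byte {p}")
            rows = np.frombuffer(buf, dtype=np.uint8, count=stride * height, offset=p)
            yield rows.reshape(height, stride)[::-1, :width]

    return FrameStream(
        frames=gen, fps=fps, width=width, height=height, n_frames=len(frame_offsets)
    )


# ---------------------------------------------------------------------------
# TIFF stacks and generic fallback
# ---------------------------------------------------------------------------

def write_tiff(stream: FrameStream, path: str | Path) -> None:
    """Write a FrameStream as a multi-page grayscale TIFF stack."""
    import tifffile

    tifffile.imwrite(path, stream.load(), photometric="minisblack")


def _read_tiff(path: Path, fps_override: float | None) -> FrameStream:
    import tifffile

    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surfaced as a decode error
        raise VideoDecodeError(f"{path}: failed to decode TIFF stack ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if fps_override is None or fps_override <= 0:
        raise VideoDecodeError(
            f"{path}: TIFF stacks carry no frame rate; pass fps explicitly "
            "(fps_override / --fps-override)"
        )
    frames = np.stack([to_grayscale(f) for f in arr])
    return FrameStream.from_array(frames, fps=fps_override)


def _read_imageio(path: Path, fps_override: float | None) -> FrameStream:
    try:
        import imageio.v3 as iio

        frames = [to_grayscale(f) for f in iio.imiter(path)]
        meta = iio.immeta(path)
    except Exception as exc:  # noqa: BLE001
        raise VideoDecodeError(
            f"{path}: no available backend could decode this file ({exc}); "
            "supported directly: uncompressed 8-bit AVI, multi-page TIFF"
        ) from exc
    if not frames:
        raise VideoDecodeError(f"{path}: file decodes to zero frames")
    fps = fps_override or float(meta.get("fps") or 0)
    if fps <= 0:
        raise VideoDecodeError(
            f"{path}: container reports no frame rate; pass fps explicitly"
        )
    return FrameStream.from_array(np.stack(frames), fps=fps)


def read_video(path: str | Path, fps_override: float | None = None) -> FrameStream:
    """Read a video file into a :class:`FrameStream` of grayscale frames.

    AVI files are parsed directly (uncompressed 8-bit); ``.tif``/``.tiff``
    stacks go through tifffile (and require ``fps_override``); anything else is
    attempted through imageio. Unreadable or empty files raise
    :class:`VideoDecodeError` naming the path.
    """
    p = Path(path)
    if not p.exists():
        raise VideoDecodeError(f"{p}: file does not exist")
    if p.stat().st_size == 0:
        raise VideoDecodeError(f"{p}: file is empty (0 bytes)")
    suffix = p.suffix.lower()
    if suffix == ".avi":
        return _read_avi(p, fps_override)
    if suffix in (".tif", ".tiff"):
        return _read_tiff(p, fps_override)
    return _read_imageio(p, fps_override)
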