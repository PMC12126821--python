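"""Frame and mask I/O.

The in-memory unit consumed by every stage is :class:`FrameSequence`: an
ordered stack of 8-bit frames, grayscale ``(n, H, W)`` or color
``(n, H, W, 3)``, with a nominal frame rate.

Coordinate convention (used package-wide): 0-based, origin at the top-left,
x rightward (column index), y downward (row index). All reported coordinates
are ``(x, y)``.

Lossless round-trips go through PNG frame directories; video containers
(mp4/avi/mov/wmv/mkv/flv) are delegated to imageio's ffmpeg plugin when it is
installed, and GIF writing is always available through Pillow.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import (
    ConfigurationError,
    DecodeError,
    EmptyInputError,
    ShapeMismatchError,
)

VIDEO_EXTENSIONS = {".mp4", ".avi", ".mov", ".wmv", ".mkv", ".flv"}
FRAME_EXTENSIONS = {".png", ".jpg", ".jpeg"}

# ITU-R 601 luma weights for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered 8-bit frames sharing one geometry.

    Parameters
    ----------
    frames
        ``(n, H, W)`` grayscale or ``(n, H, W, 3)`` color uint8 array.
    fps
        Effective frames per second (source fps divided by the sampling
        interval when frames were subsampled on read).
    """

    frames: np.ndarray
    fps: float = 15.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim not in (3, 4) or (arr.ndim == 4 and arr.shape[-1] != 3):
            raise ShapeMismatchError(
                f"frames must be (n, H, W) or (n, H, W, 3); got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise EmptyInputError("a FrameSequence needs at least one frame")
        if arr.dtype != np.uint8:
            arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def to_gray(self) -> "FrameSequence":
        """ITU-R 601 luma conversion; a no-op for grayscale input."""
        if not self.is_color:
            return self
        gray = np.round(self.frames.astype(np.float64) @ _LUMA)
        return FrameSequence(np.clip(gray, 0, 255).astype(np.uint8), fps=self.fps)

    def to_color(self) -> "FrameSequence":
        if self.is_color:
            return self
        return FrameSequence(np.repeat(self.frames[..., None], 3, axis=-1), fps=self.fps)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class RegionMask:
    """Binary region-of-interest restriction.

    Any nonzero source pixel is inside. A mask whose dimensions differ from
    the frames' is rejected, never resized: silent resampling would corrupt
    the pixel-area metrics downstream.
    """

    mask: np.ndarray
    inside_count: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask) != 0
        if m.ndim != 2:
            raise ShapeMismatchError(f"mask must be 2-D; got shape {m.shape}")
        if not m.any():
            raise EmptyInputError("region mask has no inside pixels")
        self.mask = m
        self.inside_count = int(m.sum())

    @property
    def shape(self) -> tuple:
        return self.mask.shape


def _ffmpeg_available() -> bool:
    try:
        import imageio_ffmpeg  # noqa: F401

        return True
    except ImportError:
        return False


def _read_frame_dir(path: Path, interval_n: int, fps: float) -> FrameSequence:
    names = sorted(
        p for p in os.listdir(path) if Path(p).suffix.lower() in FRAME_EXTENSIONS
    )
    if not names:
        raise EmptyInputError(f"no image frames found in directory {path}")
    kept = names[::interval_n]
    frames = []
    shape = None
    for name in kept:
        img = iio.imread(path / name)
        if img.ndim == 3 and img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ShapeMismatchError(
                f"frame {name} has shape {img.shape}, expected {shape}"
            )
        frames.append(img.astype(np.uint8))
    return FrameSequence(np.stack(frames), fps=fps / interval_n)


def _read_container(path: Path, interval_n: int) -> FrameSequence:
    if not _ffmpeg_available():
        raise DecodeError(
            f"reading {path.suffix} containers requires the imageio-ffmpeg "
            "codec backend, which is not installed; use a PNG frame directory"
        )
    import imageio

    try:
        reader = imageio.get_reader(str(path))
    except Exception as exc:  # pragma: no cover - backend specific
        raise DecodeError(f"could not decode {path}: {exc}") from exc
    meta = reader.get_meta_data()
    src_fps = float(meta.get("fps", 15.0))
    frames = [
        np.asarray(frame)[..., :3].astype(np.uint8)
        for i, frame in enumerate(reader)
        if i % interval_n == 0
    ]
    reader.close()
    if not frames:
        raise EmptyInputError(f"zero frames decoded from {path}")
    return FrameSequence(np.stack(frames), fps=src_fps / interval_n)


def read_video(path, interval_n: int = 1, fps: float = 15.0) -> FrameSequence:
    """Read a video container or an ordered PNG/JPEG frame directory.

    Keeps frames whose source index is congruent to 0 modulo ``interval_n``
    (every *n*-th frame, the first always kept) and records the effective
    frame rate ``source_fps / interval_n``. Directory frames are ordered
    lexicographically, so filenames must be zero-padded.

    Parameters
    ----------
    interval_n
        Sampling interval (default 1 = every frame).
    fps
        Assumed source frame rate for frame directories, which carry none.
    """
    if interval_n < 1:
        raise ConfigurationError(f"interval must be >= 1, got {interval_n}")
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"input path does not exist: {path}")
    if path.is_dir():
        return _read_frame_dir(path, interval_n, fps)
    if path.suffix.lower() in VIDEO_EXTENSIONS:
        return _read_container(path, interval_n)
    if path.suffix.lower() in FRAME_EXTENSIONS:
        img = iio.imread(path)
        if img.ndim == 3 and img.shape[-1] == 4:
            img = img[..., :3]
        return FrameSequence(img[None].astype(np.uint8), fps=fps)
    raise DecodeError(f"unsupported input container: {path.suffix!r}")


def read_mask(path, expected_shape: tuple) -> RegionMask:
    """Load a binary region mask and check it against the frame geometry.

    Any nonzero pixel of the source image is inside the region. Color masks
    are accepted (any nonzero channel counts).
    """
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    if img.shape != tuple(expected_shape):
        raise ShapeMismatchError(
            f"mask dimensions {img.shape} do not match frame dimensions "
            f"{tuple(expected_shape)}"
        )
    return RegionMask(img)


def write_image(path, image: np.ndarray) -> None:
    """Write an 8- or 16-bit image; PNG round-trips are bit-exact."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype not in (np.uint8, np.uint16):
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def write_video(path, seq: FrameSequence) -> None:
    """Write a FrameSequence as .gif (always available) or .mp4 (needs ffmpeg).

    Video codecs are lossy; tests that need bit-exactness must use PNG frame
    directories instead.
    """
    path = Path(path)
    if seq.n_frames < 1:  # defensive; FrameSequence already enforces this
        raise EmptyInputError("cannot write an empty video")
    color = seq.to_color()
    suffix = path.suffix.lower()
    if suffix == ".gif":
        duration_ms = int(round(1000.0 / max(seq.fps, 1e-6)))
        iio.imwrite(path, list(color.frames), duration=duration_ms, loop=0)
    elif suffix in VIDEO_EXTENSIONS:
        if not _ffmpeg_available():
            raise DecodeError(
                f"writing {suffix} requires the imageio-ffmpeg codec backend; "
                "write a .gif or a PNG frame directory instead"
            )
        import imageio

        writer = imageio.get_writer(str(path), fps=max(seq.fps, 1.0))
        for frame in color:
            writer.append_data(frame)
        writer.close()
    else:
        raise DecodeError(f"unsupported video output container: {suffix!r}")


def write_frame_dir(path, seq: FrameSequence) -> None:
    """Write frames as zero-padded PNGs (the lossless video path)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(seq.n_frames - 1)))
    for i, frame in enumerate(seq):
        iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)

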