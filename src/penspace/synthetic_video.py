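"""Synthetic scenes with analytically known motion ground truth.

Every downstream stage (background subtraction, accumulation, occupancy
metrics, range estimation) is validated against scenes generated here, whose
foreground support is known by construction: scripted blobs (disks or
squares of fixed integer geometry) move over a constant background corrupted
by optional Gaussian pixel noise and salt/pepper impulses.

Rasterisation is exact integer geometry so that oracles are unambiguous: a
pixel belongs to a disk iff its integer center ``(px, py)`` satisfies
``(px - x)**2 + (py - y)**2 <= r**2``; squares are axis-aligned with side
``2 r + 1``.

Randomness is a single stream per scene, consumed in a documented fixed
order (per frame: Gaussian noise field, then impulse field, each drawn only
when its parameter is nonzero), which makes rendering bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import BoundsError, ConfigurationError
from .video_io import FrameSequence, write_frame_dir, write_image

#: minimum contrast between blob and background so foreground is detectable
#: by construction
MIN_CONTRAST = 30


@dataclass
class BlobScript:
    """A scripted moving blob.

    ``trajectory`` lists ``(frame_index, x_center, y_center)`` with strictly
    increasing frame indices; the blob is drawn only on listed frames.
    ``intensity`` may be a single grey level or one per trajectory point
    (a "textured" animal whose brightness varies frame to frame).
    """

    blob_id: int
    trajectory: Sequence[Tuple[int, float, float]]
    radius: int
    intensity: object = 200
    shape: str = "disk"

    def __post_init__(self) -> None:
        frames = [t[0] for t in self.trajectory]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ConfigurationError(
                f"blob {self.blob_id}: trajectory frame indices must be "
                "strictly increasing"
            )
        if self.shape not in ("disk", "square"):
            raise ConfigurationError(
                f"blob {self.blob_id}: shape must be 'disk' or 'square'"
            )
        if np.isscalar(self.intensity):
            self.intensity = [int(self.intensity)] * len(self.trajectory)
        elif len(self.intensity) != len(self.trajectory):
            raise ConfigurationError(
                f"blob {self.blob_id}: need one intensity per trajectory point"
            )
        else:
            self.intensity = [int(v) for v in self.intensity]

    def positions(self) -> Dict[int, Tuple[float, float, int]]:
        """frame_index -> (x, y, intensity)."""
        return {
            f: (x, y, v)
            for (f, x, y), v in zip(self.trajectory, self.intensity)
        }


@dataclass
class SceneSpec:
    """Scene geometry and noise model.

    ``noise_sigma`` is the Gaussian pixel-noise standard deviation in grey
    levels; ``salt_pepper_rate`` is the per-pixel-per-frame probability of an
    impulse (split evenly between salt=255 and pepper=0).
    """

    width: int = 64
    height: int = 64
    n_frames: int = 100
    background_value: int = 60
    noise_sigma: float = 0.0
    salt_pepper_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ConfigurationError("scene must be at least 16x16 pixels")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not (0 <= self.salt_pepper_rate < 0.05):
            raise ConfigurationError("salt_pepper_rate must be in [0, 0.05)")
        if self.n_frames < 1:
            raise ConfigurationError("need at least 1 frame")


def rasterise_blob(shape: str, x: float, y: float, radius: int,
                   width: int, height: int) -> np.ndarray:
    """Boolean support of one blob on the pixel grid (no bounds check)."""
    yy, xx = np.mgrid[0:height, 0:width]
    if shape == "disk":
        return (xx - x) ** 2 + (yy - y) ** 2 <= radius ** 2
    half = radius
    return (np.abs(xx - np.round(x)) <= half) & (np.abs(yy - np.round(y)) <= half)


def _check_bounds(spec: SceneSpec, blob: BlobScript) -> None:
    for f, x, y in blob.trajectory:
        if f < 0 or f >= spec.n_frames:
            raise BoundsError(
                f"blob {blob.blob_id}: frame index {f} outside scene "
                f"(0..{spec.n_frames - 1})"
            )
        r = blob.radius
        if x - r < 0 or x + r > spec.width - 1 or y - r < 0 or y + r > spec.height - 1:
            raise BoundsError(
                f"blob {blob.blob_id} leaves frame bounds at frame {f}: "
                f"center ({x}, {y}), radius {r}, frame {spec.width}x{spec.height}"
            )


def _check_contrast(spec: SceneSpec, blob: BlobScript) -> None:
    for v in blob.intensity:
        if abs(v - spec.background_value) < MIN_CONTRAST:
            raise ConfigurationError(
                f"blob {blob.blob_id}: intensity {v} is within "
                f"{MIN_CONTRAST} grey levels of background "
                f"{spec.background_value}; foreground must be detectable"
            )


def render_scene(spec: SceneSpec, blobs: Sequence[BlobScript] = ()) -> FrameSequence:
    """Render the scene to an 8-bit grayscale FrameSequence.

    Per frame: background + clipped Gaussian noise, then salt/pepper
    impulses, then blob pixels overwritten by blob intensity. Deterministic
    for a fixed ``spec.seed``.
    """
    for blob in blobs:
        _check_bounds(spec, blob)
        _check_contrast(spec, blob)
    rng = np.random.default_rng(spec.seed)
    positions = [b.positions() for b in blobs]
    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=np.uint8)
    for t in range(spec.n_frames):
        frame = np.full((spec.height, spec.width), float(spec.background_value))
        if spec.noise_sigma > 0:
            frame += rng.normal(0.0, spec.noise_sigma, frame.shape)
        frame = np.clip(np.round(frame), 0, 255)
        if spec.salt_pepper_rate > 0:
            u = rng.random(frame.shape)
            frame[u < spec.salt_pepper_rate / 2] = 255
            frame[(u >= spec.salt_pepper_rate / 2) & (u < spec.salt_pepper_rate)] = 0
        for blob, pos in zip(blobs, positions):
            if t in pos:
                x, y, v = pos[t]
                support = rasterise_blob(blob.shape, x, y, blob.radius,
                                         spec.width, spec.height)
                frame[support] = v
        frames[t] = frame.astype(np.uint8)
    return FrameSequence(frames, fps=15.0)


def blob_support_at(spec: SceneSpec, blobs: Sequence[BlobScript],
                    frame_index: int) -> np.ndarray:
    """Boolean union of blob supports on one frame (the per-frame truth)."""
    out = np.zeros((spec.height, spec.width), dtype=bool)
    for blob in blobs:
        pos = blob.positions()
        if frame_index in pos:
            x, y, _ = pos[frame_index]
            out |= rasterise_blob(blob.shape, x, y, blob.radius,
                                  spec.width, spec.height)
    return out


def ground_truth_union(spec: SceneSpec, blobs: Sequence[BlobScript]) -> np.ndarray:
    """Union over all frames of blob supports: the analytic "region used"."""
    for blob in blobs:
        _check_bounds(spec, blob)
    out = np.zeros((spec.height, spec.width), dtype=bool)
    for t in range(spec.n_frames):
        out |= blob_support_at(spec, blobs, t)
    return out


def linear_trajectory(start: Tuple[float, float], end: Tuple[float, float],
                      frames: Sequence[int]) -> List[Tuple[int, float, float]]:
    """Integer-rounded linear interpolation between two points."""
    frames = list(frames)
    n = len(frames)
    if n == 1:
        return [(frames[0], start[0], start[1])]
    return [
        (
            f,
            float(np.round(start[0] + (end[0] - start[0]) * i / (n - 1))),
            float(np.round(start[1] + (end[1] - start[1]) * i / (n - 1))),
        )
        for i, f in enumerate(frames)
    ]


def write_scene(outdir, spec: SceneSpec, blobs: Sequence[BlobScript],
                write_mp4: bool = False) -> None:
    """Write frames (lossless PNGs), ground-truth mask PNG and trajectory JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = render_scene(spec, blobs)
    write_frame_dir(outdir / "frames", seq)
    truth = ground_truth_union(spec, blobs)
    write_image(outdir / "ground_truth.png", truth.astype(np.uint8) * 255)
    meta = {
        "scene": {
            "width": spec.width, "height": spec.height,
            "n_frames": spec.n_frames,
            "background_value": spec.background_value,
            "noise_sigma": spec.noise_sigma,
            "salt_pepper_rate": spec.salt_pepper_rate, "seed": spec.seed,
        },
        "blobs": [
            {
                "blob_id": b.blob_id, "radius": b.radius, "shape": b.shape,
                "intensity": list(b.intensity),
                "trajectory": [list(map(float, t)) for t in b.trajectory],
            }
            for b in blobs
        ],
    }
    (outdir / "trajectories.json").write_text(json.dumps(meta, indent=2))
    if write_mp4:
        from .video_io import write_video

        write_video(outdir / "scene.mp4", seq)
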