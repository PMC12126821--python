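"""From per-frame foreground masks to cumulative motion and centroids.

Fixed stage order: subtract -> apply_mask -> morphological_open ->
{accumulate, extract_centroids}. The region mask restricts detection before
noise filtering; opening (erosion then dilation with a k x k square element)
removes components smaller than the element; surviving binary masks are
summed into the cumulative motion map, and connected components above the
area threshold contribute one centroid each to the track.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, EmptyInputError, ShapeMismatchError
from .video_io import FrameSequence, RegionMask, write_image

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class MorphParams:
    """Opening kernel: k x k square structuring element; k odd, k=1 = identity."""

    kernel_size: int = 3

    def validate(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError(
                f"morphology kernel size must be odd and >= 1, got "
                f"{self.kernel_size}"
            )


@dataclass
class CentroidParams:
    """Connected-component filter for centroid extraction.

    ``area_threshold`` is a minimum component area in px^2: components
    smaller than it are treated as noise and yield no centroid. One centroid
    is taken per surviving component (group-housed animals form several
    disjoint regions).
    """

    area_threshold: float = 50.0
    connectivity: int = 8

    def validate(self) -> None:
        if self.area_threshold < 0:
            raise ConfigurationError("area_threshold must be >= 0")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")


@dataclass
class CumulativeMotionMap:
    """Per-pixel count of frames in which motion was detected."""

    counts: np.ndarray
    frames_processed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ShapeMismatchError("counts must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def save(self, png_path, sidecar_path=None) -> None:
        """16-bit PNG plus a JSON sidecar recording frames_processed."""
        if self.counts.max(initial=0) > 65535:
            raise ValueError("counts exceed 16-bit range")
        write_image(png_path, self.counts.astype(np.uint16))
        sidecar = Path(sidecar_path or Path(png_path).with_suffix(".json"))
        sidecar.write_text(json.dumps({
            "frames_processed": self.frames_processed,
            "height": self.counts.shape[0],
            "width": self.counts.shape[1],
        }, indent=2) + "\n")


@dataclass
class CentroidTrack:
    """Accumulated per-frame centroids of detected motion components.

    Entries are ``(frame_index, x, y, component_area)`` with sub-pixel
    centroid coordinates; ``grid_points()`` rounds half-up to the pixel grid
    for density estimation.
    """

    entries: List[Tuple[int, float, float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["frame", "x", "y", "area"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def points(self) -> np.ndarray:
        """(n, 2) array of sub-pixel (x, y) centroid positions."""
        if not self.entries:
            return np.empty((0, 2))
        return np.array([(e[1], e[2]) for e in self.entries], dtype=float)

    def grid_points(self) -> np.ndarray:
        """Centroids rounded half-up to integer pixel coordinates."""
        return np.floor(self.points() + 0.5).astype(np.int64)


def apply_mask(mask_frame: np.ndarray, region: RegionMask) -> np.ndarray:
    """Restrict a motion mask to the region of interest (pixelwise AND)."""
    mask_frame = np.asarray(mask_frame) != 0
    if mask_frame.shape != region.shape:
        raise ShapeMismatchError(
            f"motion mask shape {mask_frame.shape} does not match region "
            f"shape {region.shape}"
        )
    return mask_frame & region.mask


def morphological_open(mask_frame: np.ndarray, params: MorphParams) -> np.ndarray:
    """Erosion then dilation with a k x k square element (outside = 0)."""
    params.validate()
    mask_frame = np.asarray(mask_frame) != 0
    k = params.kernel_size
    if k == 1:
        return mask_frame.copy()
    structure = np.ones((k, k), dtype=bool)
    return ndimage.binary_opening(mask_frame, structure=structure)


def accumulate(masks: Iterable[np.ndarray]) -> CumulativeMotionMap:
    """Sum binary masks into the cumulative motion map."""
    counts = None
    n = 0
    for m in masks:
        m = np.asarray(m) != 0
        if counts is None:
            counts = np.zeros(m.shape, dtype=np.int64)
        elif m.shape != counts.shape:
            raise ShapeMismatchError(
                f"mask shape {m.shape} does not match accumulator shape "
                f"{counts.shape}"
            )
        counts += m
        n += 1
    if counts is None:
        raise EmptyInputError("accumulate() received no masks")
    return CumulativeMotionMap(counts, frames_processed=n)


def extract_centroids(mask_frame: np.ndarray, params: CentroidParams,
                      frame_index: int) -> List[Tuple[int, float, float, float]]:
    """Centroids of connected components with area >= the threshold.

    Component centroid = (mean column, mean row) of its pixels, real-valued.
    """
    params.validate()
    mask_frame = np.asarray(mask_frame) != 0
    structure = _STRUCTURE_8 if params.connectivity == 8 else _STRUCTURE_4
    labels, n_comp = ndimage.label(mask_frame, structure=structure)
    if n_comp == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n_comp + 1)[1:]
    keep = np.flatnonzero(areas >= params.area_threshold) + 1
    if keep.size == 0:
        return []
    centers = ndimage.center_of_mass(mask_frame, labels, keep)  # (row, col)
    return [
        (frame_index, float(c), float(r), float(areas[lab - 1]))
        for (r, c), lab in zip(centers, keep)
    ]


@dataclass
class PipelineResult:
    """Output bundle of the masking/accumulation stage."""

    cumulative: CumulativeMotionMap
    track: CentroidTrack
    masks: Optional[np.ndarray] = None  # (n, H, W) opened masks, if kept


def process_frames(frames: FrameSequence, subtractor,
                   region: Optional[RegionMask] = None,
                   morph: Optional[MorphParams] = None,
                   centroid: Optional[CentroidParams] = None,
                   keep_masks: bool = False) -> PipelineResult:
    """Run subtract -> mask -> open -> {accumulate, centroids} over a sequence."""
    morph = morph or MorphParams()
    centroid = centroid or CentroidParams()
    morph.validate()
    centroid.validate()
    gray = frames.to_gray()
    if region is not None and region.shape != (gray.height, gray.width):
        raise ShapeMismatchError(
            f"region shape {region.shape} does not match frame shape "
            f"{(gray.height, gray.width)}"
        )
    counts = np.zeros((gray.height, gray.width), dtype=np.int64)
    track = CentroidTrack()
    kept = [] if keep_masks else None
    for t, frame in enumerate(gray):
        m = np.asarray(subtractor.apply(frame)) != 0
        if region is not None:
            m = apply_mask(m, region)
        m = morphological_open(m, morph)
        counts += m
        track.entries.extend(extract_centroids(m, centroid, t))
        if kept is not None:
            kept.append(m)
    cumulative = CumulativeMotionMap(counts, frames_processed=gray.n_frames)
    masks = np.stack(kept) if kept else None
    return PipelineResult(cumulative=cumulative, track=track, masks=masks)
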