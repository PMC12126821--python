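"""Rendering of space-use distribution maps.

Cumulative counts are min-max normalised to 8 bits, mapped through a
256-entry colormap LUT (bone, ocean, pink or hot, taken from matplotlib),
and blended over the original frame with weights alpha (frame) and beta
(heat). Peaks are annotated with the conventional symbols — black circle
(first), red square (second), blue triangle (third) — and the core/full
ranges are drawn as translucent fills with the full range's convex hull as
a closed polyline.

All functions are pure with respect to the analysis outputs: they return
new images and never mutate maps, tracks or range estimates.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib
import numpy as np
from PIL import Image, ImageDraw

from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptyInputError,
    ShapeMismatchError,
)
from .motion_pipeline import CumulativeMotionMap
from .space_metrics import PeakSet, RangeEstimate
from .video_io import FrameSequence

COLORMAP_NAMES = ("bone", "ocean", "pink", "hot")

# marker geometry: radius / half-side in px, stroke width in px
MARKER_RADIUS = 8
MARKER_STROKE = 2

_MARKER_COLORS = {1: (0, 0, 0), 2: (255, 0, 0), 3: (0, 0, 255)}


def get_lut(name: str) -> np.ndarray:
    """256 x 3 uint8 lookup table for a supported colormap name."""
    if name not in COLORMAP_NAMES:
        raise ConfigurationError(
            f"unknown colormap {name!r}; valid names: {', '.join(COLORMAP_NAMES)}"
        )
    cmap = matplotlib.colormaps[name]
    lut = cmap(np.linspace(0.0, 1.0, 256))[:, :3]
    return np.round(lut * 255).astype(np.uint8)


def normalise_counts(cmap: CumulativeMotionMap,
                     max_count: Optional[int] = None) -> np.ndarray:
    """Min-max scale counts to 8 bits: v' = round(255 v / max).

    ``max_count`` overrides the map's own maximum (used by the video path,
    which normalises every frame by the running maximum so late frames do
    not dim early ones). An all-zero map stays all-zero.
    """
    counts = cmap.counts
    if counts.size == 0:
        raise EmptyInputError("empty cumulative map")
    m = int(counts.max()) if max_count is None else int(max_count)
    if m <= 0:
        return np.zeros(counts.shape, dtype=np.uint8)
    return np.round(255.0 * counts / m).astype(np.uint8)


def apply_colormap(intensity: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Per-pixel LUT lookup of an 8-bit intensity image."""
    intensity = np.asarray(intensity)
    if intensity.dtype != np.uint8:
        raise ConfigurationError("apply_colormap expects an 8-bit image")
    if lut.shape != (256, 3):
        raise ConfigurationError("LUT must have exactly 256 RGB entries")
    return lut[intensity]


def blend(frame: np.ndarray, heat: np.ndarray, alpha: float = 0.7,
          beta: float = 0.7) -> np.ndarray:
    """Weighted sum out = clip(round(alpha*frame + beta*heat), 0, 255)."""
    if alpha + beta <= 0:
        raise ConfigurationError("alpha + beta must be > 0")
    frame = np.asarray(frame)
    heat = np.asarray(heat)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    if frame.shape != heat.shape:
        raise ShapeMismatchError(
            f"frame shape {frame.shape} does not match heat shape {heat.shape}"
        )
    out = alpha * frame.astype(np.float64) + beta * heat.astype(np.float64)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def annotate_peaks(image: np.ndarray, peaks: PeakSet,
                   radius: int = MARKER_RADIUS,
                   stroke: int = MARKER_STROKE) -> np.ndarray:
    """Draw rank markers: black circle, red square, blue triangle (up).

    Ranks flagged insufficient are left unmarked. Only pixels within the
    marker bounding boxes are touched.
    """
    img = Image.fromarray(np.ascontiguousarray(np.asarray(image)))
    if img.mode != "RGB":
        img = img.convert("RGB")
    draw = ImageDraw.Draw(img)
    for p in peaks.peaks:
        color = _MARKER_COLORS[p.rank]
        x, y, r = p.x, p.y, radius
        if p.rank == 1:
            draw.ellipse([x - r, y - r, x + r, y + r], outline=color,
                         width=stroke)
        elif p.rank == 2:
            draw.rectangle([x - r, y - r, x + r, y + r], outline=color,
                           width=stroke)
        else:
            # equilateral-ish triangle pointing up, inscribed in the radius
            pts = [(x, y - r), (x - r, y + r), (x + r, y + r)]
            draw.line(pts + [pts[0]], fill=color, width=stroke)
    return np.asarray(img)


def render_range_map(frame: np.ndarray, ranges: RangeEstimate,
                     core_color=(220, 40, 40), full_color=(40, 120, 220),
                     hull_color=(255, 220, 0), fill_alpha: float = 0.35) -> np.ndarray:
    """Core/full ranges as translucent fills plus the full-range hull polyline.

    A degenerate estimate returns the frame with a text badge only.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    out = frame.astype(np.float64).copy()
    if ranges.degenerate:
        img = Image.fromarray(out.astype(np.uint8))
        draw = ImageDraw.Draw(img)
        draw.text((4, 4), "no range estimate", fill=(255, 0, 0))
        return np.asarray(img)
    for region, color in ((ranges.full_region, full_color),
                          (ranges.core_region, core_color)):
        sel = np.asarray(region, dtype=bool)
        out[sel] = (1 - fill_alpha) * out[sel] + fill_alpha * np.array(color)
    img = Image.fromarray(np.clip(np.round(out), 0, 255).astype(np.uint8))
    if len(ranges.hull) >= 2:
        draw = ImageDraw.Draw(img)
        pts = [tuple(map(float, p)) for p in ranges.hull]
        draw.line(pts + [pts[0]], fill=hull_color, width=2)
    return np.asarray(img)


def render_video(frames: FrameSequence, masks: np.ndarray, alpha: float = 0.7,
                 beta: float = 0.7, colormap: str = "hot") -> FrameSequence:
    """Space-use distribution map video.

    Frame t is the blend of the original frame t with the colormapped
    cumulative map accumulated through frame t; each frame is normalised by
    the running maximum count. The final video frame therefore equals the
    final still image (before annotation).
    """
    masks = np.asarray(masks)
    if masks.shape[0] != frames.n_frames:
        raise AlignmentError(
            f"{frames.n_frames} frames but {masks.shape[0]} per-frame masks"
        )
    lut = get_lut(colormap)
    color = frames.to_color()
    counts = np.zeros((frames.height, frames.width), dtype=np.int64)
    out = np.empty((frames.n_frames, frames.height, frames.width, 3),
                   dtype=np.uint8)
    for t in range(frames.n_frames):
        counts += masks[t] != 0
        running = CumulativeMotionMap(counts, frames_processed=t + 1)
        heat = apply_colormap(normalise_counts(running), lut)
        out[t] = blend(color[t], heat, alpha, beta)
    return FrameSequence(out, fps=frames.fps)


def render_still(frame: np.ndarray, cmap: CumulativeMotionMap,
                 peaks: Optional[PeakSet] = None, alpha: float = 0.7,
                 beta: float = 0.7, colormap: str = "hot") -> np.ndarray:
    """The annotated space-use distribution map image."""
    lut = get_lut(colormap)
    heat = apply_colormap(normalise_counts(cmap), lut)
    out = blend(frame, heat, alpha, beta)
    if peaks is not None:
        out = annotate_peaks(out, peaks)
    return out
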