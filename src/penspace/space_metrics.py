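"""Space-use metrics: peaks, occupancy percentages, KDE ranges, summary.

The cumulative motion map yields the three highest-intensity pixel
locations, the percentage of the view with any detected motion (total and
per quadrant), and — through a Gaussian kernel density estimate over the
accumulated centroid positions — the core range (smallest region holding
50% of density mass) and full range (95%), reported as pixel areas with the
full range's convex hull.

"Top p% of density" is interpreted as mass-based isopleths, the standard
core-area / home-range convention in ecology: the smallest set of grid
cells whose cumulative density reaches the stated fraction. A value-based
threshold (cells above (1 - p) of the peak density) is available behind the
``method`` switch for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import ConfigurationError, DegenerateTrackError, EmptyInputError
from .motion_pipeline import CentroidTrack, CumulativeMotionMap
from .video_io import RegionMask

#: rank -> (marker symbol, color) used in figures and the summary table
PEAK_SYMBOLS = {1: ("circle", "black"), 2: ("square", "red"),
                3: ("triangle", "blue")}


@dataclass
class Peak:
    rank: int
    x: int
    y: int
    intensity: int


@dataclass
class PeakSet:
    """The top-n most active pixel locations (n=3 by convention).

    Ranks whose intensity would be zero are flagged insufficient instead of
    reported.
    """

    peaks: List[Peak]
    insufficient: List[int] = field(default_factory=list)
    symbols: dict = field(default_factory=lambda: dict(PEAK_SYMBOLS))


@dataclass
class QuadrantReport:
    """Occupancy percentages: total view plus the four quadrants.

    Q1 = upper right, Q2 = upper left, Q3 = lower left, Q4 = lower right.
    Each percentage is active pixels over that region's own pixel count.
    """

    total_pct: float
    q1_pct: float
    q2_pct: float
    q3_pct: float
    q4_pct: float


@dataclass
class RangeParams:
    """Core/full range estimation parameters.

    ``bandwidth_rule``: 'scott' (n^(-1/6) times the mean per-axis sample
    standard deviation; Silverman's rule coincides with Scott's in two
    dimensions and is accepted as an alias) or 'fixed' with
    ``fixed_bandwidth`` in pixels. ``method``: 'mass' (isopleths, default)
    or 'value' (threshold at (1 - mass) of peak density).
    """

    core_mass: float = 0.50
    full_mass: float = 0.95
    bandwidth_rule: str = "scott"
    fixed_bandwidth: Optional[float] = None
    method: str = "mass"

    def validate(self) -> None:
        if not (0 < self.core_mass < self.full_mass < 1):
            raise ConfigurationError(
                f"need 0 < core_mass < full_mass < 1, got "
                f"{self.core_mass}, {self.full_mass}"
            )
        if self.bandwidth_rule not in ("scott", "silverman", "fixed"):
            raise ConfigurationError(
                f"unknown bandwidth rule {self.bandwidth_rule!r}; "
                "valid: scott, silverman, fixed"
            )
        if self.bandwidth_rule == "fixed" and (
            self.fixed_bandwidth is None or self.fixed_bandwidth <= 0
        ):
            raise ConfigurationError("fixed bandwidth rule needs fixed_bandwidth > 0")
        if self.method not in ("mass", "value"):
            raise ConfigurationError("method must be 'mass' or 'value'")


@dataclass
class RangeEstimate:
    """KDE density surface with core/full regions, areas and hull."""

    density: np.ndarray
    core_region: np.ndarray
    full_region: np.ndarray
    core_area: int
    full_area: int
    hull: List[Tuple[float, float]]
    degenerate: bool = False
    bandwidth: float = float("nan")


def top_peaks(cmap: CumulativeMotionMap, n: int = 3) -> PeakSet:
    """The n highest-count pixels; ties broken row-major (smaller y, then x).

    Pixels with zero count never rank; missing ranks are flagged.
    """
    counts = cmap.counts
    if counts.size == 0:
        raise EmptyInputError("empty cumulative map")
    H, W = counts.shape
    flat = counts.ravel()
    # lexsort: last key is primary. Row-major flat index is the tie-break.
    order = np.argsort(-flat, kind="stable")
    peaks: List[Peak] = []
    insufficient: List[int] = []
    for rank in range(1, n + 1):
        idx = order[rank - 1] if rank - 1 < flat.size else None
        if idx is None or flat[idx] <= 0:
            insufficient.append(rank)
            continue
        y, x = divmod(int(idx), W)
        peaks.append(Peak(rank=rank, x=x, y=y, intensity=int(flat[idx])))
    return PeakSet(peaks=peaks, insufficient=insufficient)


def percent_region_used(cmap: CumulativeMotionMap,
                        region: Optional[RegionMask] = None,
                        mask_denominator: bool = False) -> float:
    """100 * active pixels / total pixels in the view.

    Active = count > 0. The denominator is the full view by default; with
    ``mask_denominator=True`` and a region supplied, the region's inside
    pixel count is used instead.
    """
    counts = cmap.counts
    active = counts > 0
    if region is not None:
        active = active & region.mask
    denom = region.inside_count if (mask_denominator and region is not None) \
        else counts.size
    return 100.0 * int(active.sum()) / denom


def _quadrant_slices(H: int, W: int):
    """Q1..Q4 as (row-slice, col-slice); center row/col go bottom/right."""
    hm, wm = H // 2, W // 2
    return {
        1: (slice(0, hm), slice(wm, W)),    # upper right
        2: (slice(0, hm), slice(0, wm)),    # upper left
        3: (slice(hm, H), slice(0, wm)),    # lower left
        4: (slice(hm, H), slice(wm, W)),    # lower right
    }


def quadrant_percentages(cmap: CumulativeMotionMap,
                         region: Optional[RegionMask] = None,
                         mask_denominator: bool = False) -> QuadrantReport:
    """Per-quadrant occupancy with the same active-pixel logic as the total.

    The view splits at floor(H/2) / floor(W/2); for odd dimensions the
    center row/column belongs to the bottom/right quadrants, so the four
    quadrants partition the view exactly.
    """
    counts = cmap.counts
    H, W = counts.shape
    active = counts > 0
    if region is not None:
        active = active & region.mask
    pcts = {}
    for q, (rs, cs) in _quadrant_slices(H, W).items():
        if mask_denominator and region is not None:
            denom = int(region.mask[rs, cs].sum())
        else:
            denom = (rs.stop - rs.start) * (cs.stop - cs.start)
        pcts[q] = 100.0 * int(active[rs, cs].sum()) / denom if denom else 0.0
    total = percent_region_used(cmap, region, mask_denominator)
    return QuadrantReport(total_pct=total, q1_pct=pcts[1], q2_pct=pcts[2],
                          q3_pct=pcts[3], q4_pct=pcts[4])


def _bandwidth(points: np.ndarray, params: RangeParams) -> float:
    if params.bandwidth_rule == "fixed":
        return float(params.fixed_bandwidth)
    # Scott's rule for d=2 (Silverman's coincides): n^(-1/6) * mean axis std.
    n = points.shape[0]
    stds = points.std(axis=0, ddof=1)
    h = n ** (-1.0 / 6.0) * float(stds.mean())
    return max(h, 1e-3)


def kde_density(track: CentroidTrack, params: RangeParams,
                shape: Tuple[int, int]) -> Tuple[np.ndarray, float]:
    """Isotropic Gaussian KDE of centroid positions on the pixel grid.

    Centroids are rounded half-up onto the grid, binned, and smoothed with
    an isotropic Gaussian of the rule's bandwidth; the surface is
    renormalised to sum to 1 over the grid (mass smoothed off the edge is
    folded back by the normalisation).

    Returns (density, bandwidth). Raises DegenerateTrackError for fewer
    than two distinct positions.
    """
    params.validate()
    H, W = shape
    pts = track.grid_points()
    if pts.shape[0] == 0 or np.unique(pts, axis=0).shape[0] < 2:
        raise DegenerateTrackError(
            "kernel density estimation needs at least 2 distinct centroid "
            f"positions; got {np.unique(pts, axis=0).shape[0] if pts.size else 0}"
        )
    h = _bandwidth(track.points(), params)
    hist = np.zeros((H, W), dtype=np.float64)
    xs = np.clip(pts[:, 0], 0, W - 1)
    ys = np.clip(pts[:, 1], 0, H - 1)
    np.add.at(hist, (ys, xs), 1.0)
    density = ndimage.gaussian_filter(hist, sigma=h, mode="constant",
                                      truncate=6.0)
    total = density.sum()
    if total <= 0:
        raise DegenerateTrackError("density surface vanished")
    return density / total, h


def density_ranges(density: np.ndarray, params: RangeParams) -> RangeEstimate:
    """Core (50%) and full (95%) ranges of a normalised density surface.

    Mass method: grid cells sorted by density descending (row-major
    tie-break); each region is the smallest prefix whose cumulative mass
    reaches the target fraction. Areas are cell counts; the hull is the
    convex hull of the full region's cell centers in (x, y).
    """
    params.validate()
    density = np.asarray(density, dtype=np.float64)
    H, W = density.shape
    total = density.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ConfigurationError("density surface must be normalised to sum 1")
    if params.method == "value":
        dmax = density.max()
        core = density >= (1.0 - params.core_mass) * dmax
        full = density >= (1.0 - params.full_mass) * dmax
    else:
        flat = density.ravel()
        order = np.argsort(-flat, kind="stable")
        cum = np.cumsum(flat[order])
        # smallest prefix with cumulative mass >= target (float-safe)
        n_core = int(np.searchsorted(cum, params.core_mass * total - 1e-12) + 1)
        n_full = int(np.searchsorted(cum, params.full_mass * total - 1e-12) + 1)
        core = np.zeros(flat.size, dtype=bool)
        full = np.zeros(flat.size, dtype=bool)
        core[order[:n_core]] = True
        full[order[:n_full]] = True
        core = core.reshape(H, W)
        full = full.reshape(H, W)
    full |= core  # containment guaranteed for both methods
    ys, xs = np.nonzero(full)
    hull = convex_hull(list(zip(xs.tolist(), ys.tolist()))) if xs.size else []
    return RangeEstimate(
        density=density, core_region=core, full_region=full,
        core_area=int(core.sum()), full_area=int(full.sum()), hull=hull,
    )


def degenerate_range(shape: Tuple[int, int]) -> RangeEstimate:
    """Placeholder estimate when the centroid track cannot support a KDE."""
    H, W = shape
    z = np.zeros((H, W))
    return RangeEstimate(density=z, core_region=z.astype(bool),
                         full_region=z.astype(bool), core_area=0,
                         full_area=0, hull=[], degenerate=True)


def estimate_ranges(track: CentroidTrack, params: RangeParams,
                    shape: Tuple[int, int]) -> RangeEstimate:
    """KDE + isopleths, degrading gracefully on a degenerate track."""
    try:
        density, h = kde_density(track, params, shape)
    except DegenerateTrackError:
        return degenerate_range(shape)
    est = density_ranges(density, params)
    est.bandwidth = h
    return est


def convex_hull(points: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """Convex hull vertices in counter-clockwise order, collinear points excluded.

    Degenerate inputs (one point, two points, or all collinear) return the
    extreme points.
    """
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if pts.shape[0] == 0:
        raise EmptyInputError("convex hull of no points")
    if pts.shape[0] <= 2:
        return [tuple(p) for p in pts]
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # all collinear: the two extremes along the line (lexicographic)
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        return [tuple(pts[order[0]]), tuple(pts[order[-1]])]
    return [tuple(pts[v]) for v in hull.vertices]


@dataclass
class MotionSummary:
    """The 10-row summary table.

    Rows, in order: peak 1..3 (symbol, color, coordinates, intensity),
    total occupancy %, Q1..Q4 occupancy %, core-range area and full-range
    area in pixels. A flag column marks insufficient-activity peaks and
    degenerate range estimates.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        path = str(path)
        self.table.to_json(path, orient="records", indent=2)

    def __repr__(self) -> str:
        return self.table.to_string(index=False)


def build_summary(peaks: PeakSet, quadrants: QuadrantReport,
                  ranges: RangeEstimate) -> MotionSummary:
    """Assemble the summary table from the three computed metric sets."""
    rows = []
    by_rank = {p.rank: p for p in peaks.peaks}
    for rank in (1, 2, 3):
        symbol, color = PEAK_SYMBOLS[rank]
        p = by_rank.get(rank)
        rows.append({
            "metric": f"peak_{rank}", "symbol": symbol, "color": color,
            "x": p.x if p else "", "y": p.y if p else "",
            "value": p.intensity if p else 0,
            "flag": "" if p else "insufficient_activity",
        })
    for name, value in [("total_pct", quadrants.total_pct),
                        ("q1_pct", quadrants.q1_pct),
                        ("q2_pct", quadrants.q2_pct),
                        ("q3_pct", quadrants.q3_pct),
                        ("q4_pct", quadrants.q4_pct)]:
        rows.append({"metric": name, "symbol": "", "color": "", "x": "",
                     "y": "", "value": value, "flag": ""})
    rflag = "degenerate_track" if ranges.degenerate else ""
    rows.append({"metric": "core_area_px", "symbol": "", "color": "", "x": "",
                 "y": "", "value": ranges.core_area, "flag": rflag})
    rows.append({"metric": "full_area_px", "symbol": "", "color": "", "x": "",
                 "y": "", "value": ranges.full_area, "flag": rflag})
    return MotionSummary(pd.DataFrame(rows))
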