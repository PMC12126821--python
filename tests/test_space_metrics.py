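"""Peaks, occupancy percentages, KDE ranges, convex hull, summary table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from penspace.errors import ConfigurationError, DegenerateTrackError
from penspace.motion_pipeline import CentroidTrack, CumulativeMotionMap
from penspace.space_metrics import (
    RangeParams,
    build_summary,
    convex_hull,
    degenerate_range,
    density_ranges,
    estimate_ranges,
    kde_density,
    percent_region_used,
    quadrant_percentages,
    top_peaks,
)
from penspace.video_io import RegionMask

from _oracles import brute_hull_vertices


def cmap_from(counts):
    counts = np.asarray(counts)
    return CumulativeMotionMap(counts, frames_processed=int(counts.max(initial=0)) or 1)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def test_top_peaks_direct_ordering():
    counts = np.zeros((8, 8), dtype=int)
    counts[3, 4] = 10
    counts[1, 1] = 7
    counts[5, 5] = 5
    ps = top_peaks(cmap_from(counts))
    assert [(p.x, p.y, p.intensity) for p in ps.peaks] == [
        (4, 3, 10), (1, 1, 7), (5, 5, 5)]
    assert ps.insufficient == []


def test_top_peaks_tie_break_row_major():
    counts = np.zeros((8, 8), dtype=int)
    counts[0, 2] = 10  # (x=2, y=0)
    counts[2, 0] = 10  # (x=0, y=2)
    ps = top_peaks(cmap_from(counts))
    assert (ps.peaks[0].x, ps.peaks[0].y) == (2, 0)  # smaller y ranks first
    assert (ps.peaks[1].x, ps.peaks[1].y) == (0, 2)


def test_top_peaks_flags_insufficient_activity():
    counts = np.zeros((8, 8), dtype=int)
    counts[4, 4] = 3
    ps = top_peaks(cmap_from(counts))
    assert len(ps.peaks) == 1 and ps.insufficient == [2, 3]


@settings(max_examples=50, deadline=None)
@given(counts=arrays(np.int64, (12, 12), elements=st.integers(0, 20)))
def test_top_peaks_matches_exhaustive_sort_oracle(counts):
    ps = top_peaks(cmap_from(counts))
    H, W = counts.shape
    cells = [(int(counts[y, x]), y, x) for y in range(H) for x in range(W)]
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))
    expected = [(x, y, v) for v, y, x in cells[:3] if v > 0]
    assert [(p.x, p.y, p.intensity) for p in ps.peaks] == expected


# ---------------------------------------------------------------------------
# occupancy percentages
# ---------------------------------------------------------------------------

def test_percent_region_used_formula():
    assert percent_region_used(cmap_from(np.zeros((10, 10)))) == 0.0
    counts = np.zeros((10, 10), dtype=int)
    counts[:5, :5] = 2
    assert percent_region_used(cmap_from(counts)) == 25.0


def test_percent_region_used_mask_denominator():
    counts = np.zeros((10, 10), dtype=int)
    counts[0, :5] = 1
    region = np.zeros((10, 10))
    region[:, :5] = 1
    cm = cmap_from(counts)
    assert percent_region_used(cm, RegionMask(region)) == 5.0
    assert percent_region_used(cm, RegionMask(region),
                               mask_denominator=True) == 10.0


def test_quadrant_split_even_dims():
    counts = np.zeros((4, 4), dtype=int)
    counts[:2, :2] = 1  # top-left block = Q2
    q = quadrant_percentages(cmap_from(counts))
    assert (q.q2_pct, q.q1_pct, q.q3_pct, q.q4_pct) == (100.0, 0.0, 0.0, 0.0)
    uniform = quadrant_percentages(cmap_from(np.ones((4, 4), dtype=int)))
    assert (uniform.q1_pct, uniform.q2_pct, uniform.q3_pct,
            uniform.q4_pct) == (100.0,) * 4


@settings(max_examples=50, deadline=None)
@given(counts=arrays(np.int64, (5, 5), elements=st.integers(0, 3)))
def test_quadrants_match_exhaustive_partition_oracle_odd_dims(counts):
    """5x5 view: left quadrants get 2 columns, right get 3; every pixel is
    assigned to exactly one quadrant and the active counts are conserved."""
    q = quadrant_percentages(cmap_from(counts))
    active = counts > 0
    # exhaustive per-pixel assignment: top = y < 2, left = x < 2
    tallies = {1: [0, 0], 2: [0, 0], 3: [0, 0], 4: [0, 0]}
    for y in range(5):
        for x in range(5):
            top, left = y < 2, x < 2
            quad = 2 if (top and left) else 1 if top else 3 if left else 4
            tallies[quad][0] += int(active[y, x])
            tallies[quad][1] += 1
    for quad, pct in ((1, q.q1_pct), (2, q.q2_pct), (3, q.q3_pct),
                      (4, q.q4_pct)):
        a, n = tallies[quad]
        assert pct == pytest.approx(100.0 * a / n, abs=1e-12)
    total_active = sum(t[0] for t in tallies.values())
    assert total_active == int(active.sum())
    assert q.total_pct == pytest.approx(100.0 * total_active / 25, abs=1e-12)


# ---------------------------------------------------------------------------
# KDE and ranges
# ---------------------------------------------------------------------------

def track_from_points(pts):
    return CentroidTrack([(i, float(x), float(y), 1.0)
                          for i, (x, y) in enumerate(pts)])


def test_kde_unimodal_at_repeated_point():
    pts = [(20, 20)] * 50 + [(21, 20)]  # jitter to pass the precondition
    density, h = kde_density(track_from_points(pts),
                             RangeParams(bandwidth_rule="fixed",
                                         fixed_bandwidth=1.5), (40, 40))
    assert density.sum() == pytest.approx(1.0, abs=1e-9)
    y, x = np.unravel_index(np.argmax(density), density.shape)
    assert (x, y) == (20, 20)


def test_kde_mass_splits_between_two_far_clusters(rng):
    a = rng.normal([16, 32], 1.5, size=(100, 2))
    b = rng.normal([48, 32], 1.5, size=(100, 2))
    density, _ = kde_density(track_from_points(np.vstack([a, b])),
                             RangeParams(), (64, 64))
    left = density[:, :32].sum()
    assert left == pytest.approx(0.5, abs=0.05)


def test_kde_correlates_with_analytic_gaussian_surface(rng):
    pts = rng.normal([32, 32], 6.0, size=(1000, 2))
    density, h = kde_density(track_from_points(pts), RangeParams(), (64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    s2 = 6.0 ** 2 + h ** 2  # sample spread convolved with the kernel
    analytic = np.exp(-((xx - 32.0) ** 2 + (yy - 32.0) ** 2) / (2 * s2))
    r = np.corrcoef(density.ravel(), analytic.ravel())[0, 1]
    assert r >= 0.99


def test_kde_degenerate_track_raises():
    with pytest.raises(DegenerateTrackError):
        kde_density(track_from_points([(5, 5)] * 10), RangeParams(), (16, 16))
    with pytest.raises(DegenerateTrackError):
        kde_density(CentroidTrack(), RangeParams(), (16, 16))


def test_uniform_density_prefix_sizes_exact():
    for H, W in ((10, 10), (7, 9)):
        density = np.full((H, W), 1.0 / (H * W))
        est = density_ranges(density, RangeParams())
        n = H * W
        assert est.core_area == int(np.ceil(0.50 * n))
        assert est.full_area == int(np.ceil(0.95 * n))


def test_core_region_contained_in_full_region(rng):
    pts = rng.normal([32, 32], 5.0, size=(300, 2))
    est = estimate_ranges(track_from_points(pts), RangeParams(), (64, 64))
    assert (est.full_region[est.core_region]).all()
    assert est.core_area <= est.full_area


def test_full_region_monotone_in_mass_parameter(rng):
    pts = rng.normal([32, 32], 5.0, size=(300, 2))
    track = track_from_points(pts)
    prev = None
    for full_mass in (0.6, 0.8, 0.95):
        est = estimate_ranges(track, RangeParams(full_mass=full_mass),
                              (64, 64))
        if prev is not None:
            assert (est.full_region[prev]).all()  # never shrinks
        prev = est.full_region
    assert est.density.sum() == pytest.approx(1.0, abs=1e-9)


def test_small_bandwidth_isopleth_ratio_approaches_gaussian_limit(rng):
    """For a bivariate isotropic Gaussian the 50%/95% isopleth area ratio is
    ln(0.5)/ln(0.05) ~ 0.2314 (chi-square with 2 df)."""
    pts = rng.normal([64, 64], 14.0, size=(1000, 2))
    est = estimate_ranges(
        track_from_points(pts),
        RangeParams(bandwidth_rule="fixed", fixed_bandwidth=0.5), (128, 128))
    ratio = est.core_area / est.full_area
    assert ratio == pytest.approx(np.log(0.5) / np.log(0.05), abs=0.03)


def test_value_threshold_method_available(rng):
    pts = rng.normal([32, 32], 5.0, size=(300, 2))
    density, _ = kde_density(track_from_points(pts), RangeParams(), (64, 64))
    est = density_ranges(density, RangeParams(method="value"))
    assert 0 < est.core_area <= est.full_area


def test_range_params_validation():
    with pytest.raises(ConfigurationError):
        RangeParams(core_mass=0.95, full_mass=0.5).validate()
    with pytest.raises(ConfigurationError):
        RangeParams(bandwidth_rule="fixed").validate()
    with pytest.raises(ConfigurationError):
        RangeParams(bandwidth_rule="magic").validate()


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------

def test_hull_square_plus_center():
    pts = [(0, 0), (4, 0), (4, 4), (0, 4), (2, 2)]
    hull = convex_hull(pts)
    assert set(hull) == {(0.0, 0.0), (4.0, 0.0), (4.0, 4.0), (0.0, 4.0)}


def test_hull_collinear_points_reduce_to_endpoints():
    pts = [(i, 2 * i) for i in range(5)]
    assert set(convex_hull(pts)) == {(0.0, 0.0), (4.0, 8.0)}


def test_hull_degenerate_inputs():
    assert convex_hull([(3, 3)]) == [(3.0, 3.0)]
    assert set(convex_hull([(1, 1), (2, 5)])) == {(1.0, 1.0), (2.0, 5.0)}


def test_hull_vertices_counter_clockwise(rng):
    pts = rng.random((50, 2)) * 100
    hull = convex_hull(pts)
    area2 = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area2 += x1 * y2 - x2 * y1
    assert area2 > 0  # positive signed area = CCW vertex order


def test_hull_matches_brute_force_oracle(rng):
    pts = rng.random((200, 2)) * 100
    assert set(convex_hull(pts)) == brute_hull_vertices(pts)


# ---------------------------------------------------------------------------
# summary assembly
# ---------------------------------------------------------------------------

def test_summary_has_ten_ordered_rows(rng):
    counts = rng.integers(0, 50, size=(32, 32))
    cm = cmap_from(counts)
    peaks = top_peaks(cm)
    quad = quadrant_percentages(cm)
    pts = rng.normal([16, 16], 4.0, size=(200, 2))
    ranges = estimate_ranges(track_from_points(pts), RangeParams(), (32, 32))
    table = build_summary(peaks, quad, ranges).table
    assert list(table["metric"]) == [
        "peak_1", "peak_2", "peak_3", "total_pct", "q1_pct", "q2_pct",
        "q3_pct", "q4_pct", "core_area_px", "full_area_px"]
    # every cell equals the standalone operation's output
    assert table.loc[0, "value"] == peaks.peaks[0].intensity
    assert table.loc[3, "value"] == quad.total_pct
    assert table.loc[8, "value"] == ranges.core_area
    assert table.loc[9, "value"] == ranges.full_area
    ivals = [table.loc[i, "value"] for i in range(3)]
    assert ivals == sorted(ivals, reverse=True)


def test_summary_flags_degenerate_track():
    counts = np.zeros((16, 16), dtype=int)
    cm = cmap_from(counts)
    table = build_summary(top_peaks(cm), quadrant_percentages(cm),
                          degenerate_range((16, 16))).table
    assert (table.loc[8:9, "value"] == 0).all()
    assert (table.loc[8:9, "flag"] == "degenerate_track").all()
    assert (table.loc[0:2, "flag"] == "insufficient_activity").all()
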