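# Methods

## Problem and pipeline

`penspace` quantifies group-level space use from a fixed overhead camera.
It does not track individuals; the unit of analysis is the pixel, and the
central statistic is the cumulative motion map — for every pixel, the
number of processed frames in which motion was detected there. The fixed
stage order is:

1. decode frames (optionally every *n*-th frame only; skipped frames never
   reach the background model),
2. grayscale conversion (ITU-R 601 luma; the original color frame is kept
   for rendering),
3. per-frame background subtraction → binary motion mask,
4. restriction to the region-of-interest mask (pixelwise AND),
5. morphological opening (erosion then dilation, k×k square element),
6. accumulation into the cumulative map, and extraction of
   connected-component centroids (area ≥ τ) into the centroid track,
7. metrics: peaks, occupancy percentages, KDE core/full ranges,
8. rendering: colormap, α/β blend, annotation, video assembly.

Coordinates are 0-based, origin top-left, reported as (x, y) with x the
column and y the row.

## Background models

All three models are online, per-pixel, and deterministic given
(parameters, seed). The vectorised implementations follow documented
scalar recursions exactly — the test suite re-implements each as a plain
per-pixel loop and asserts bit-for-bit agreement — so the recursion
details below are normative.

**Gaussian mixture (`mog2`).** K components per pixel with weight, mean,
variance. Components are ranked by w/σ (stable sort); the new value
matches the first component within d standard deviations. Classification
uses the pre-update model: background components are the smallest ranked
prefix with cumulative weight ≥ T; a pixel is foreground iff unmatched or
matched outside that prefix. Matched update: all weights decay by (1−a),
the matched one gains a; with ρ = a/w (updated weight) and δ = x − μ
(pre-update mean), μ += ρδ and σ² += ρ(δ²−σ²). On no match the
lowest-weight component is replaced by (w=a, μ=x, σ²=σ_init²). Variances
are floored at σ_min² and weights renormalised every frame. The component
count is fixed (no adaptive selection): it keeps the scalar reference
exact and the behaviour analysable. Defaults: K=5, a=0.01, d=2.5, T=0.8,
σ_init=15, σ_min=4 — the classical literature values for this model
family; all configurable.

**Pixel history (`knn`).** N stored samples per pixel (initialised from
the first frame); background iff ≥ k_min samples lie within the distance
threshold. Background pixels refresh a uniformly chosen buffer slot with
probability p_update; the uniform and slot fields are drawn once per frame
from the run-seeded generator, in a fixed order, which is what makes runs
reproducible. Defaults: N=20, k_min=4, threshold=20, p_update=0.05.

**Stability counter (`cnt`).** Counter c and stable value v per pixel; a
change beyond the threshold resets c and v, otherwise c increments;
background iff c ≥ min_stability. Defaults: min_stability=15,
threshold=10. This model detects *change*, not presence: an animal that
stops moving is absorbed after min_stability frames, and vacated pixels
ghost as foreground for min_stability frames. Consequently a
constant-intensity object in continuous motion cannot be tracked at high
IoU by any parameterisation — the ghost trail scales with
speed × min_stability while hole-freeness requires min_stability to exceed
the per-pixel coverage time. The detection-quality fixtures therefore use
a *textured* blob (intensity alternating between two values ≥ 30 grey
levels from background, emulating an animal whose appearance varies frame
to frame) and run `cnt` with min_stability=1 there, which bounds the ghost
to the single-frame vacated strip.

GMG, LSBP and GSOC are not implemented natively; they dispatch through the
external-backend adapter (`external:<id>` entry points) when such a
backend is installed.

## Metrics

**Peaks.** The three highest-count pixels, ties broken row-major (smaller
y, then smaller x) — a deterministic rule is mandatory and the choice is
arbitrary. No minimum separation is imposed: adjacent pixels may all rank.
Ranks that would have zero count are flagged `insufficient_activity`.

**Occupancy.** Active = count > 0. Total occupancy divides by the full
view's pixel count (an optional mode divides by the region mask's inside
count instead). Quadrants split at floor(W/2)/floor(H/2); for odd
dimensions the center row/column belongs to the bottom/right quadrants, so
the quadrants partition the view exactly and active counts are conserved.
Each quadrant's percentage uses that quadrant's own pixel count.

**Ranges.** Motion-component centroids (sub-pixel in the track, rounded
half-up onto the pixel grid for density estimation) feed a binned
isotropic Gaussian KDE evaluated on the pixel grid and renormalised to sum
to 1 (edge-truncated mass is folded back by the normalisation; the filter
is truncated at 6σ). Bandwidth: Scott's rule for two dimensions,
h = n^(−1/6) · mean(per-axis sample SD, ddof=1), floored at 10⁻³ px;
Silverman's rule coincides with Scott's at d=2 and is accepted as an
alias; a fixed bandwidth can be supplied. "Top 50%/95% of density" is read
as mass-based isopleths — the smallest cell set holding that fraction of
total mass, the standard core-area/home-range convention in ecology —
with cells sorted by density descending (row-major tie-break) and the
prefix chosen by cumulative mass ≥ target (with a 10⁻¹² slack against
float rounding). A value-threshold variant (cells ≥ (1−mass)·peak) exists
behind the `method` switch for comparison. Fewer than two distinct
centroid positions is a degenerate track: areas are reported as 0 with a
flag rather than an error at the summary level.

**Convex hull.** Computed by Qhull (scipy) on the full-range cell centers;
vertices counter-clockwise, collinear boundary points excluded; one/two
point and all-collinear inputs degrade to the extreme points.

## Synthetic scenes

The generator renders scripted disk/square blobs (exact integer
rasterisation: a pixel is in a disk iff its center satisfies the circle
inequality) over a constant background with optional clipped Gaussian
noise and salt/pepper impulses, one seeded stream consumed in a fixed
per-frame order (noise, then impulses) for bit-reproducibility. Blob
intensity must differ from background by ≥ 30 grey levels so foreground is
detectable by construction. Ground truth (per-frame support and its union)
is computed analytically, never by running the pipeline.

What the scenes emulate: moving animals of roughly constant size, optional
frame-to-frame appearance variation (textured blobs), sensor noise,
impulse noise. What they do not: shadows, gradual illumination drift,
occlusion, perspective, compression artifacts. Passing tests therefore
demonstrate algorithmic correctness of the implementations and metrics,
not field robustness on barn video.

Problem sizes used by the tests and the acceptance script: 32×32×100
scenes for bit-level oracle equivalence, 64×64×150 for detection quality
(50-frame empty burn-in, 5 frames of entry settling, IoU measured on the
remaining 95 frames), 96×96×120 for the demo, n=1000 centroids on a
128×128 grid for the isopleth-ratio check — sizes at which the scalar
oracles and brute-force geometry checks are exact and fast.

## Numerical and design choices

- Counts are min-max normalised to 8 bits before colormapping (the map's
  maximum → 255); the per-frame video normalises by the running maximum so
  late frames do not dim early ones. Colormap LUTs (bone, ocean, pink,
  hot) are sampled from matplotlib at 256 entries; tests pin endpoints and
  luminance trend rather than exact LUT bytes.
- Blend: out = clip(round(α·frame + β·heat)), single pass, uint8; defaults
  α = β = 0.7 (configurable; only α+β > 0 is required).
- Marker geometry: radius/half-side 8 px, stroke 2 px, triangle pointing
  up.
- Centroid threshold τ is a minimum connected-component area in px²
  (default 50, 8-connectivity): its purpose is noise filtering, and
  per-component centroids (not one per frame) reflect that a group of
  animals forms several disjoint motion regions.
- The region mask is applied before opening, and a mask of the wrong
  dimensions is rejected rather than resized — silent resampling would
  corrupt pixel-area metrics.
- The still space-use image blends against the last processed frame; the
  video blends frame t against frame t, so the last video frame equals the
  still image before annotation.
- The opening treats pixels outside the frame as empty (border value 0).

## Limitations

- Group-level only: no identities, no trajectories, no per-animal
  statistics.
- Occupancy is resolution-dependent (pixel counts, not metric areas); use
  a fixed camera geometry when comparing runs.
- The KDE operates on detected motion centroids, so stationary animals
  contribute nothing: "range" here is a range of *activity*, not of
  presence.
- mp4 I/O requires the optional ffmpeg backend; without it the CLI reads
  frame directories and writes GIF video (recorded in the manifest).
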