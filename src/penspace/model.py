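"""Model/Results interface over the motion-analysis pipeline.

:class:`MotionAnalysis` is built from a :class:`~penspace.video_io.FrameSequence`
(or a video path via :meth:`MotionAnalysis.from_video`) plus the analysis
parameters; :meth:`MotionAnalysis.fit` runs background subtraction, mask
restriction, morphological opening, accumulation and centroid extraction,
then computes peaks, occupancy percentages and the KDE core/full ranges,
returning a :class:`MotionResults` whose :meth:`~MotionResults.summary` is
the 10-row metrics table. Rendering (still map, range map, video) hangs off
the results object.

Example
-------
>>> from penspace import MotionAnalysis, synthetic_video as sv
>>> spec = sv.SceneSpec(width=64, height=64, n_frames=80, seed=7)
>>> blob = sv.BlobScript(0, sv.linear_trajectory((12, 12), (30, 20),
...                      range(80)), radius=5, intensity=200)
>>> res = MotionAnalysis(sv.render_scene(spec, [blob])).fit()
>>> res.summary().table.shape
(10, 7)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __about__
from .background_subtraction import Subtractor, make_subtractor
from .errors import ConfigurationError
from .motion_pipeline import (
    CentroidParams,
    CentroidTrack,
    CumulativeMotionMap,
    MorphParams,
    process_frames,
)
from .space_metrics import (
    MotionSummary,
    PeakSet,
    QuadrantReport,
    RangeEstimate,
    RangeParams,
    build_summary,
    estimate_ranges,
    quadrant_percentages,
    top_peaks,
)
from .video_io import FrameSequence, RegionMask, read_mask, read_video
from .visualization import render_range_map, render_still, render_video


class MotionAnalysis:
    """Group-level motion analysis of an overhead video.

    Parameters
    ----------
    frames
        The input :class:`FrameSequence` (color or grayscale).
    region
        Optional :class:`RegionMask` restricting detection.
    algorithm
        ``mog2`` (default), ``knn``, ``cnt`` or ``external:<id>``.
    algorithm_params
        Per-algorithm parameter overrides (see
        :mod:`penspace.background_subtraction`).
    kernel_size
        Morphological opening kernel (odd; 1 disables opening).
    area_threshold
        Minimum connected-component area (px^2) for a centroid.
    connectivity
        Component connectivity, 4 or 8.
    core_mass, full_mass
        Density-mass fractions of the core and full range.
    bandwidth_rule, fixed_bandwidth
        KDE bandwidth selection (see :class:`RangeParams`).
    seed
        Seed for the stochastic parts of the analysis (KNN buffer refresh).
    """

    def __init__(self, frames: FrameSequence,
                 region: Optional[RegionMask] = None,
                 algorithm: str = "mog2",
                 algorithm_params: Optional[dict] = None,
                 kernel_size: int = 3,
                 area_threshold: float = 50.0,
                 connectivity: int = 8,
                 core_mass: float = 0.50,
                 full_mass: float = 0.95,
                 bandwidth_rule: str = "scott",
                 fixed_bandwidth: Optional[float] = None,
                 seed: int = 0):
        if not isinstance(frames, FrameSequence):
            frames = FrameSequence(np.asarray(frames))
        self.frames = frames
        self.region = region
        self.algorithm = algorithm
        self.algorithm_params = dict(algorithm_params or {})
        self.morph = MorphParams(kernel_size=kernel_size)
        self.centroid = CentroidParams(area_threshold=area_threshold,
                                       connectivity=connectivity)
        self.range_params = RangeParams(core_mass=core_mass,
                                        full_mass=full_mass,
                                        bandwidth_rule=bandwidth_rule,
                                        fixed_bandwidth=fixed_bandwidth)
        self.seed = int(seed)
        # fail fast on bad configuration
        self.morph.validate()
        self.centroid.validate()
        self.range_params.validate()

    @classmethod
    def from_video(cls, path, mask_path=None, interval_n: int = 1,
                   fps: float = 15.0, **kwargs) -> "MotionAnalysis":
        """Build the model straight from a video file or frame directory."""
        frames = read_video(path, interval_n=interval_n, fps=fps)
        region = None
        if mask_path is not None:
            region = read_mask(mask_path, (frames.height, frames.width))
        return cls(frames, region=region, **kwargs)

    def _make_subtractor(self) -> Subtractor:
        return make_subtractor(self.algorithm, self.algorithm_params,
                               seed=self.seed)

    def fit(self, keep_masks: bool = False) -> "MotionResults":
        """Run the full pipeline and compute every summary metric."""
        pipeline = process_frames(
            self.frames, self._make_subtractor(), region=self.region,
            morph=self.morph, centroid=self.centroid, keep_masks=keep_masks,
        )
        peaks = top_peaks(pipeline.cumulative)
        quadrants = quadrant_percentages(pipeline.cumulative, self.region)
        ranges = estimate_ranges(pipeline.track, self.range_params,
                                 pipeline.cumulative.shape)
        return MotionResults(self, pipeline.cumulative, pipeline.track,
                             peaks, quadrants, ranges, masks=pipeline.masks)


class MotionResults:
    """Fitted motion-analysis results.

    Attributes
    ----------
    cumulative_map : CumulativeMotionMap
    centroid_track : CentroidTrack
    peaks : PeakSet
    quadrants : QuadrantReport
    ranges : RangeEstimate
    masks : ndarray or None
        Per-frame opened masks, present when ``fit(keep_masks=True)``.
    """

    def __init__(self, model: MotionAnalysis, cumulative: CumulativeMotionMap,
                 track: CentroidTrack, peaks: PeakSet,
                 quadrants: QuadrantReport, ranges: RangeEstimate,
                 masks: Optional[np.ndarray] = None):
        self.model = model
        self.cumulative_map = cumulative
        self.centroid_track = track
        self.peaks = peaks
        self.quadrants = quadrants
        self.ranges = ranges
        self.masks = masks

    @property
    def frames_processed(self) -> int:
        return self.cumulative_map.frames_processed

    def summary(self) -> MotionSummary:
        """The 10-row summary table (peaks, occupancy, range areas)."""
        return build_summary(self.peaks, self.quadrants, self.ranges)

    # -- rendering ---------------------------------------------------------

    def _reference_frame(self) -> np.ndarray:
        # the last processed frame: the scene as most recently seen
        return self.model.frames.to_color()[self.model.frames.n_frames - 1]

    def plot_spaceuse(self, alpha: float = 0.7, beta: float = 0.7,
                      colormap: str = "hot", annotate: bool = True) -> np.ndarray:
        """Annotated space-use distribution map image (H x W x 3 uint8)."""
        return render_still(self._reference_frame(), self.cumulative_map,
                            self.peaks if annotate else None,
                            alpha=alpha, beta=beta, colormap=colormap)

    def plot_range_map(self) -> np.ndarray:
        """Core/full-range map with the full-range convex hull."""
        return render_range_map(self._reference_frame(), self.ranges)

    def spaceuse_video(self, alpha: float = 0.7, beta: float = 0.7,
                       colormap: str = "hot") -> FrameSequence:
        """Per-frame space-use distribution video (needs keep_masks=True)."""
        if self.masks is None:
            raise ConfigurationError(
                "per-frame masks were not kept; call fit(keep_masks=True)"
            )
        return render_video(self.model.frames, self.masks, alpha=alpha,
                            beta=beta, colormap=colormap)

    def save_manifest(self, path, extra: Optional[dict] = None) -> None:
        """Write the run manifest: full configuration + seed + version."""
        m = self.model
        manifest = {
            "software": "penspace",
            "version": __about__.__version__,
            "algorithm": m.algorithm,
            "algorithm_params": m.algorithm_params,
            "kernel_size": m.morph.kernel_size,
            "area_threshold": m.centroid.area_threshold,
            "connectivity": m.centroid.connectivity,
            "core_mass": m.range_params.core_mass,
            "full_mass": m.range_params.full_mass,
            "bandwidth_rule": m.range_params.bandwidth_rule,
            "fixed_bandwidth": m.range_params.fixed_bandwidth,
            "seed": m.seed,
            "frames_processed": self.frames_processed,
            "frame_width": m.frames.width,
            "frame_height": m.frames.height,
            "fps": m.frames.fps,
        }
        if extra:
            manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
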