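"""Shared fixture scenes with analytically known ground truth."""

import numpy as np
import pytest

from penspace import synthetic_video as sv


def make_detection_scene(seed: int = 1):
    """64x64, 150 frames: empty 50-frame burn-in, then a textured disk
    (radius 7, intensity alternating 200/220 over background 60) sweeping a
    non-self-overlapping path at 1 px/frame.

    The alternating intensity emulates a textured animal whose appearance
    changes frame to frame; it keeps counter-based (change-detecting)
    models responsive over the whole support.
    """
    pts = []
    for t in range(50, 94):
        pts.append((t, 10.0 + (t - 50), 20.0))       # rightward
    for t in range(94, 119):
        pts.append((t, 53.0, 20.0 + (t - 93)))       # downward
    for t in range(119, 150):
        pts.append((t, 53.0 - (t - 118), 45.0))      # leftward
    intensity = [200 + 20 * (t % 2) for t, _, _ in pts]
    blob = sv.BlobScript(0, pts, radius=7, intensity=intensity)
    spec = sv.SceneSpec(width=64, height=64, n_frames=150,
                        background_value=60, seed=seed)
    return spec, [blob]


def make_oracle_scene(seed: int = 2):
    """32x32, 100 frames: a small textured disk bouncing around, with a
    brief disappearance — exercises matching, replacement and re-learning in
    the per-pixel models."""
    pts = []
    for t in range(0, 30):
        pts.append((t, 6.0 + 0.5 * t, 8.0))
    for t in range(30, 60):
        pts.append((t, 21.0, 8.0 + 0.5 * (t - 30)))
    # absent frames 60-69, then returns
    for t in range(70, 100):
        pts.append((t, 21.0 - 0.4 * (t - 70), 23.0 - 0.3 * (t - 70)))
    intensity = [200 + 20 * (t % 2) for t, _, _ in pts]
    blob = sv.BlobScript(0, [(t, round(x), round(y)) for t, x, y in pts],
                         radius=3, intensity=intensity)
    spec = sv.SceneSpec(width=32, height=32, n_frames=100,
                        background_value=60, seed=seed)
    return spec, [blob]


def make_quadrant_scene(quadrant: int, width=64, height=64, n_frames=120):
    """A blob confined strictly inside one quadrant (1=UR, 2=UL, 3=LL, 4=LR),
    entering after a 40-frame empty burn-in and pacing a short loop."""
    wm, hm = width // 2, height // 2
    x0 = wm + 8 if quadrant in (1, 4) else 8
    y0 = hm + 8 if quadrant in (3, 4) else 8
    pts = []
    for i, t in enumerate(range(40, n_frames)):
        phase = i % 24
        dx = phase if phase < 12 else 23 - phase
        pts.append((t, float(x0 + dx), float(y0 + (i // 24) % 4)))
    intensity = [200 + 20 * (t % 2) for t, _, _ in pts]
    blob = sv.BlobScript(0, pts, radius=5, intensity=intensity)
    spec = sv.SceneSpec(width=width, height=height, n_frames=n_frames,
                        background_value=60, seed=3 + quadrant)
    return spec, [blob]


@pytest.fixture(scope="session")
def detection_scene():
    spec, blobs = make_detection_scene()
    return spec, blobs, sv.render_scene(spec, blobs)


@pytest.fixture(scope="session")
def oracle_scene():
    spec, blobs = make_oracle_scene()
    return spec, blobs, sv.render_scene(spec, blobs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
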