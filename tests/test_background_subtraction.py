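"""Background subtractors vs per-pixel scalar oracles and their contracts.

The principal correctness surface: the vectorised array implementations
must agree bit-for-bit with independent scalar (per-pixel loop) reference
implementations of the same documented recursions.
"""

import numpy as np
import pytest

from penspace.background_subtraction import (
    CNTParams,
    CNTSubtractor,
    KNNParams,
    KNNSubtractor,
    MOG2Params,
    MOG2Subtractor,
    make_subtractor,
)
from penspace.errors import ConfigurationError, ShapeMismatchError

from _oracles import cnt_scalar, knn_scalar, mog2_scalar


def run_subtractor(sub, frames):
    return np.stack([sub.apply(f) for f in frames])


# ---------------------------------------------------------------------------
# scalar-oracle equivalence (bit-for-bit)
# ---------------------------------------------------------------------------

def test_mog2_matches_scalar_oracle(oracle_scene):
    _, _, seq = oracle_scene
    params = MOG2Params()
    got = run_subtractor(MOG2Subtractor(params), seq.frames)
    expected = mog2_scalar(seq.frames, params)
    assert (got == expected).all()


def test_knn_matches_scalar_oracle(oracle_scene):
    _, _, seq = oracle_scene
    params = KNNParams()
    got = run_subtractor(KNNSubtractor(params, seed=77), seq.frames)
    expected = knn_scalar(seq.frames, params, seed=77)
    assert (got == expected).all()


def test_cnt_matches_scalar_oracle(oracle_scene):
    _, _, seq = oracle_scene
    params = CNTParams()
    got = run_subtractor(CNTSubtractor(params), seq.frames)
    expected = cnt_scalar(seq.frames, params)
    assert (got == expected).all()


def test_mog2_matches_scalar_oracle_on_noisy_scene(rng):
    """Noise exercises variance adaptation and component replacement."""
    frames = np.clip(
        rng.normal(100.0, 8.0, size=(40, 12, 12)), 0, 255
    ).astype(np.uint8)
    params = MOG2Params(n_components=3, learning_rate=0.05)
    got = run_subtractor(MOG2Subtractor(params), frames)
    expected = mog2_scalar(frames, params)
    assert (got == expected).all()


# ---------------------------------------------------------------------------
# analytic single-pixel behaviour
# ---------------------------------------------------------------------------

def constant_frames(value, n, shape=(4, 4)):
    return np.full((n,) + shape, value, dtype=np.uint8)


def test_constant_video_all_background_after_burn_in():
    frames = constant_frames(50, 100)
    for name in ("mog2", "knn", "cnt"):
        sub = make_subtractor(name)
        masks = run_subtractor(sub, frames)
        assert not masks[20:].any(), name


def test_mog2_flags_single_frame_jump():
    frames = constant_frames(50, 40)
    frames[20] = 200  # one-frame jump: no matching component
    masks = run_subtractor(MOG2Subtractor(), frames)
    assert masks[20].all()
    assert not masks[19].any() and not masks[21].any()


def test_mog2_absorbs_static_disk_monotonically():
    """A disk appearing on a learned background is fully detected on its
    first frame, then absorbed: foreground count never increases."""
    frames = constant_frames(60, 200, shape=(32, 32))
    yy, xx = np.mgrid[0:32, 0:32]
    disk = (xx - 16) ** 2 + (yy - 16) ** 2 <= 25
    frames[50:, disk] = 200
    masks = run_subtractor(MOG2Subtractor(), frames)
    assert (masks[50] == disk).all()
    counts = masks[50:].sum(axis=(1, 2))
    assert (np.diff(counts) <= 0).all()
    assert counts[-1] < counts[0]  # absorption actually happens at a=0.01


def test_mog2_weights_sum_to_one():
    frames = constant_frames(60, 30, shape=(8, 8))
    frames[10:, :4] = 200
    sub = MOG2Subtractor()
    for f in frames:
        sub.apply(f)
        assert np.abs(sub.weights.sum(axis=0) - 1.0).max() < 1e-9


def test_knn_zero_neighbours_is_foreground():
    frames = constant_frames(50, 30)
    frames[25] = 80  # |80-50| = 30 > threshold 20: zero close samples
    masks = run_subtractor(KNNSubtractor(KNNParams()), frames)
    assert masks[25].all()
    assert not masks[24].any()


def test_cnt_counter_arithmetic():
    params = CNTParams(min_stability=10)
    masks = run_subtractor(CNTSubtractor(params), constant_frames(50, 15))
    assert masks[:10].all()         # counter below 10
    assert not masks[10:].any()     # background from frame 10 onward


def test_cnt_alternating_pixel_always_foreground():
    frames = np.zeros((20, 4, 4), dtype=np.uint8)
    frames[1::2] = 255
    masks = run_subtractor(CNTSubtractor(CNTParams()), frames)
    assert masks.all()


def test_cnt_trailing_pixels_recover_after_min_stability(oracle_scene):
    """A vacated pixel returns to background exactly min_stability frames
    after its value restabilises."""
    frames = constant_frames(60, 30, shape=(4, 4))
    frames[10, 0, 0] = 200  # blob passes through for one frame
    masks = run_subtractor(CNTSubtractor(CNTParams(min_stability=5)), frames)
    col = masks[:, 0, 0]
    assert col[10]
    assert col[11:16].all()      # change back + 5-frame restabilisation
    assert not col[16:].any()


# ---------------------------------------------------------------------------
# construction and determinism contracts
# ---------------------------------------------------------------------------

def test_make_subtractor_defaults_and_errors():
    sub = make_subtractor("mog2", {})
    assert isinstance(sub, MOG2Subtractor)
    assert sub.params == MOG2Params()
    with pytest.raises(ConfigurationError, match="external"):
        make_subtractor("gmg", {})
    with pytest.raises(ConfigurationError, match="valid names"):
        make_subtractor("nonsense")
    with pytest.raises(ConfigurationError):
        make_subtractor("external:not-installed")
    with pytest.raises(ConfigurationError):
        make_subtractor("mog2", {"learning_rate": 2.0})
    with pytest.raises(ConfigurationError):
        make_subtractor("knn", {"k_min": 99})


def test_identical_params_and_seed_give_identical_masks(oracle_scene):
    _, _, seq = oracle_scene
    for name in ("mog2", "knn", "cnt"):
        a = run_subtractor(make_subtractor(name, seed=5), seq.frames)
        b = run_subtractor(make_subtractor(name, seed=5), seq.frames)
        assert (a == b).all(), name


def test_frame_shape_mismatch_rejected():
    for name in ("mog2", "knn", "cnt"):
        sub = make_subtractor(name)
        sub.apply(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ShapeMismatchError):
            sub.apply(np.zeros((9, 8), dtype=np.uint8))
        with pytest.raises(ShapeMismatchError):
            sub.apply(np.zeros((8, 8, 3), dtype=np.uint8))
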