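"""Pre-processing: lumen detection, guidewire removal, shifting, cropping, denoising."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octovessel import preprocess as pp


# --- lumen boundary --------------------------------------------------------

def test_lumen_exact_on_step_edge():
    """Noiseless frame with tissue starting at column 80 on every A-line."""
    frame = np.zeros((64, 120))
    frame[:, 80:] = 0.8
    boundary = pp.segment_lumen(frame, catheter_radius_px=5)
    np.testing.assert_array_equal(boundary, 80)


def test_lumen_accuracy_on_phantom(small_phantom):
    params, pullback, _, scene = small_phantom
    for fi in (0, 5):
        boundary = pp.segment_lumen(pullback.data[fi], params.catheter_radius_px)
        err = np.abs(boundary - scene.lumen_boundary[fi])
        assert err.mean() <= 3.0


def test_lumen_boundary_circular_continuity(small_phantom):
    params, pullback, _, _ = small_phantom
    jump = 3
    boundary = pp.segment_lumen(pullback.data[0], params.catheter_radius_px, jump=jump)
    steps = np.abs(np.diff(boundary))
    assert steps.max() <= jump
    assert abs(int(boundary[0]) - int(boundary[-1])) <= jump  # θ wrap


def test_lumen_error_on_empty_frame():
    with pytest.raises(ValueError, match="no lumen"):
        pp.segment_lumen(np.zeros((32, 50)), catheter_radius_px=4)


# --- guidewire -------------------------------------------------------------

def _interval_set(start, width, n):
    return set(((start + np.arange(width)) % n).tolist())


def test_guidewire_overlap_on_phantom(small_phantom):
    params, pullback, _, scene = small_phantom
    n_a = params.alines_per_frame
    hits = 0
    for fi in range(pullback.data.shape[0]):
        det = pp.detect_guidewire(pullback.data[fi], scene.lumen_boundary[fi])
        truth = _interval_set(*scene.guidewire_interval[fi], n_a)
        got = _interval_set(*det, n_a)
        if truth and len(truth & got) / len(truth) >= 0.9:
            hits += 1
    assert hits >= 0.9 * pullback.data.shape[0]


def test_guidewire_empty_on_uniform_frame():
    frame = np.full((64, 100), 0.6)
    boundary = np.full(64, 20, dtype=int)
    start, width = pp.detect_guidewire(frame, boundary)
    assert width == 0


def test_guidewire_wrap_detected_as_single_interval():
    """A dark band straddling the θ edge comes back as one circular interval."""
    rng = np.random.default_rng(0)
    n_a, n_d = 64, 100
    frame = 0.7 * rng.gamma(4.0, 0.25, size=(n_a, n_d))
    boundary = np.full(n_a, 20, dtype=int)
    shadow = [(a % n_a) for a in range(-6, 7)]  # wraps: alines 58..63 and 0..6
    for a in shadow:
        frame[a, 20:] *= 0.05
        frame[a, 18:24] = 0.95
    frame = np.clip(frame, 0, 1)
    start, width = pp.detect_guidewire(frame, boundary)
    got = _interval_set(start, width, n_a)
    truth = set(shadow)
    assert len(truth & got) / len(truth) >= 0.9
    # one contiguous circular interval by construction of the return type
    assert 0 < width < n_a


def test_guidewire_temporal_smoothing_tracks_drift(small_phantom):
    params, pullback, _, scene = small_phantom
    boundaries = scene.lumen_boundary
    dets = pp.detect_guidewire_stack(pullback.data.astype(float), boundaries)
    centers = [(s + w / 2) % params.alines_per_frame for s, w in dets]
    truth_c = [(s + w / 2) % params.alines_per_frame for s, w in scene.guidewire_interval]
    for c, t in zip(centers, truth_c):
        d = abs(c - t)
        assert min(d, params.alines_per_frame - d) <= 6


# --- pixel shift / crop ----------------------------------------------------

def test_pixel_shift_zero_boundary_is_identity(rng):
    frame = rng.random((16, 20))
    shifted, offsets, valid = pp.pixel_shift(frame, np.zeros(16, dtype=int))
    np.testing.assert_array_equal(shifted, frame)
    assert valid.all()


def test_pixel_shift_single_row_definition():
    frame = np.arange(10.0)[None, :]
    shifted, _, valid = pp.pixel_shift(frame, np.array([4]))
    np.testing.assert_array_equal(shifted[0], [4, 5, 6, 7, 8, 9, 0, 0, 0, 0])
    np.testing.assert_array_equal(valid[0], [1, 1, 1, 1, 1, 1, 0, 0, 0, 0])


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_pixel_shift_invertible_on_valid_mask(seed):
    r = np.random.default_rng(seed)
    n_a, n_d = 12, 18
    frame = r.random((n_a, n_d))
    boundary = r.integers(0, n_d, size=n_a)
    shifted, offsets, valid = pp.pixel_shift(frame, boundary)
    back = pp.unshift(shifted, offsets, n_d)
    # the inverse must reproduce the input wherever the shift kept data
    for a in range(n_a):
        np.testing.assert_array_equal(back[a, boundary[a]:], frame[a, boundary[a]:])


@pytest.mark.parametrize("depth,expected", [(360, 300), (200, 200), (300, 300)])
def test_crop_roi_depths(depth, expected):
    frame = np.ones((8, depth))
    out, padded = pp.crop_roi(frame, roi_depth=300)
    assert out.shape == (8, expected)
    assert not padded


def test_crop_roi_padding_opt_in():
    out, padded = pp.crop_roi(np.ones((4, 100)), roi_depth=300, pad_to_roi=True)
    assert out.shape == (4, 300)
    assert padded
    assert (out[:, 100:] == 0).all()


# --- denoise ---------------------------------------------------------------

def test_denoise_preserves_constant():
    out = pp.denoise(np.full((20, 20), 0.37))
    np.testing.assert_allclose(out, 0.37, atol=1e-6)


def test_denoise_impulse_gives_normalized_kernel():
    img = np.zeros((21, 21))
    img[10, 10] = 1.0
    out = pp.denoise(img, kernel=7, sigma=1.0)
    k = pp.gaussian_kernel(7, 1.0)
    np.testing.assert_allclose(out[7:14, 7:14], k, atol=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)


def test_denoise_matches_double_loop_convolution(rng):
    frame = rng.random((12, 11))
    k = pp.gaussian_kernel(7, 1.0)
    r = 3
    padded = np.pad(frame, r, mode="symmetric")  # edge-inclusive reflection
    want = np.empty_like(frame)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            want[i, j] = (padded[i : i + 7, j : j + 7] * k).sum()
    got = pp.denoise(frame, kernel=7, sigma=1.0)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_denoise_rejects_even_kernel():
    with pytest.raises(ValueError, match="odd"):
        pp.denoise(np.ones((8, 8)), kernel=6)


# --- full frame pipeline ---------------------------------------------------

def test_preprocess_frame_maps_vessels_through_offsets(small_phantom):
    """Truth vessel pixels, mapped through the stored offsets, stay inside
    the generated tube regions."""
    params, pullback, labels, scene = small_phantom
    fi = next(f for f in range(labels.data.shape[0]) if labels.data[f].any())
    pf = pp.preprocess_frame(pullback.data[fi], params.catheter_radius_px)
    shifted_truth = pp.shift_labels(labels.data[fi], pf)
    alines, depths = np.nonzero(shifted_truth)
    assert alines.size > 0
    for a, d in zip(alines[::5], depths[::5]):
        ra, rd = pf.to_raw_coords(int(a), int(d))
        assert labels.data[fi][ra, rd] == 1


def test_preprocess_frame_valid_mask_structure(small_phantom):
    params, pullback, _, _ = small_phantom
    pf = pp.preprocess_frame(pullback.data[0], params.catheter_radius_px)
    gw = set(pf.guidewire_alines().tolist())
    for a in range(pf.image.shape[0]):
        keep = pf.image.shape[1] if a not in gw else 0
        expect = np.zeros(pf.image.shape[1], dtype=bool)
        if a not in gw:
            expect[: min(pf.raw_depth - pf.lumen_offset[a], pf.image.shape[1])] = True
        np.testing.assert_array_equal(pf.valid_mask[a], expect)


def test_preprocess_is_deterministic(small_phantom):
    params, pullback, _, _ = small_phantom
    a = pp.preprocess_frame(pullback.data[1], params.catheter_radius_px)
    b = pp.preprocess_frame(pullback.data[1], params.catheter_radius_px)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.lumen_offset, b.lumen_offset)
    assert a.guidewire_interval == b.guidewire_interval


def test_step_order_is_part_of_the_contract(small_phantom):
    """Denoising before shifting does not commute with the pipeline order."""
    params, pullback, _, _ = small_phantom
    frame = pullback.data[2].astype(float)
    pf = pp.preprocess_frame(frame, params.catheter_radius_px)
    smoothed_first = pp.denoise(frame)
    shifted, _, _ = pp.pixel_shift(smoothed_first, pf.lumen_offset)
    cropped, _ = pp.crop_roi(shifted, pf.image.shape[1])
    assert not np.allclose(cropped, pf.image, atol=1e-4)
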