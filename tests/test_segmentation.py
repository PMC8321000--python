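"""Histogram analysis, thresholding, mask refinement and full segmentation."""

from itertools import groupby

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lungcad import (
    DegenerateInputError,
    EmptySegmentationWarning,
    InputError,
    LungSegmenter,
    PhantomConfig,
    compute_histogram,
    estimate_background_threshold,
    generate_stack,
    make_lung_mask,
    otsu_threshold,
    remove_background,
    segment_lungs,
)
from lungcad.segmentation import Histogram

from conftest import phantom


# ---------------------------------------------------------------- oracles


def bruteforce_otsu(values: np.ndarray) -> int:
    """Exhaustive between-class-variance scan; smallest threshold on ties."""
    values = values.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        v = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


def bruteforce_minima(counts) -> list:
    """Plateau-rule local minima via run-length grouping (independent path)."""
    runs = []
    i = 0
    for val, grp in groupby(counts):
        n = len(list(grp))
        runs.append((i, i + n - 1, val))
        i += n
    minima = []
    total = len(counts)
    for s, e, val in runs:
        if s > 0 and e < total - 1 and counts[s - 1] > val and counts[e + 1] > val:
            minima.append((s + e) // 2)
    return minima


def make_hist(counts, kappa=5) -> Histogram:
    counts = np.asarray(counts, dtype=np.int64)
    return Histogram(
        bin_step=kappa, counts=counts, bin_edges=np.arange(len(counts)) * kappa
    )


# ---------------------------------------------------------------- histogram


def test_histogram_binning_example():
    slc = np.array([[0, 4, 5, 255]], dtype=np.uint8)
    h = compute_histogram(slc, kappa=5)
    assert h.n_bins == 52  # ceil(256 / 5)
    assert h.counts[0] == 2  # 0 and 4
    assert h.counts[1] == 1  # 5
    assert h.counts[-1] == 1  # 255
    assert h.bin_upper_edge(0) == 4
    assert h.bin_upper_edge(51) == 255


def test_histogram_constant_slice():
    h = compute_histogram(np.full((6, 6), 60, np.uint8), kappa=5)
    assert h.counts[60 // 5] == 36
    assert h.counts.sum() == 36


@settings(max_examples=30, derandomize=True, deadline=None)
@given(arrays(np.uint8, (11, 7)), st.integers(1, 128))
def test_histogram_conserves_pixel_count(img, kappa):
    h = compute_histogram(img, kappa=kappa)
    assert h.counts.sum() == img.size
    assert h.n_bins == -(-256 // kappa)


def test_histogram_kappa_bounds():
    with pytest.raises(InputError):
        compute_histogram(np.zeros((4, 4), np.uint8), kappa=0)


# ------------------------------------------------- second local minimum


def test_second_minimum_simple_sequence():
    # minima at bins 1 and 3; lambda = upper edge of bin 3
    thr = estimate_background_threshold(make_hist([100, 2, 40, 3, 80, 90]))
    assert thr.lambda_bg == 4 * 5 - 1 == 19
    assert thr.lambda_source == "second_minimum"


def test_second_minimum_plateau_rule():
    # plateau 5,5,5 bounded by 100 and 90 -> one minimum at its center (bin 2);
    # second minimum at bin 5 (count 1)
    counts = [100, 5, 5, 5, 90, 1, 90]
    assert bruteforce_minima(counts) == [2, 5]
    thr = estimate_background_threshold(make_hist(counts))
    assert thr.lambda_bg == 6 * 5 - 1 == 29


def test_second_minimum_fallback_engages():
    counts = [100, 90, 80, 70, 60]  # strictly decreasing: no interior minimum
    img = np.array([[10, 10], [200, 200]], dtype=np.uint8)
    thr = estimate_background_threshold(make_hist(counts), image=img)
    assert thr.lambda_source == "otsu_fallback"
    assert thr.lambda_bg == bruteforce_otsu(img)
    with pytest.raises(InputError):
        estimate_background_threshold(make_hist(counts))


def test_second_minimum_needs_three_bins():
    with pytest.raises(InputError):
        estimate_background_threshold(make_hist([5, 5], kappa=128))


def test_second_minimum_matches_bruteforce_random():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(300):
        counts = rng.integers(0, 12, size=52)
        minima = bruteforce_minima(list(counts))
        if len(minima) < 2:
            continue
        thr = estimate_background_threshold(make_hist(counts))
        assert thr.lambda_bg == (minima[1] + 1) * 5 - 1
        checked += 1
    assert checked > 200


def test_smoothing_option_changes_the_scan():
    # with width-3 smoothing the sharp dip at bin 1 is averaged away
    counts = [100, 2, 40, 3, 80, 90]
    raw = estimate_background_threshold(make_hist(counts))
    smoothed = estimate_background_threshold(
        make_hist(counts), smooth_window=3, image=np.array([[0, 255]], np.uint8)
    )
    assert raw.lambda_source == "second_minimum"
    assert smoothed.lambda_source == "otsu_fallback"


# ----------------------------------------------------- background removal


def test_remove_background_strict_inequality():
    img = np.array([[50, 51], [49, 200]], dtype=np.uint8)
    out = remove_background(img, 50)
    # pixel == lambda is removed (0) then complemented to 255
    assert out[0, 0] == 255
    assert out[1, 0] == 255
    assert out[0, 1] == 255 - 51
    assert out[1, 1] == 255 - 200


def test_remove_background_extremes():
    img = np.array([[10, 20], [30, 40]], dtype=np.uint8)
    np.testing.assert_array_equal(remove_background(img, 0), 255 - img)
    np.testing.assert_array_equal(remove_background(img, 255), np.full((2, 2), 255))


# ------------------------------------------------------------------ Otsu


def test_otsu_bimodal_matches_oracle():
    img = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(np.uint8)
    img = img.reshape(10, 10)
    t = otsu_threshold(img)
    assert t == bruteforce_otsu(img)
    assert 10 <= t < 200


def test_otsu_two_extreme_values_tie_rule():
    img = np.array([[0, 255], [0, 255]], dtype=np.uint8)
    assert otsu_threshold(img) == 0  # all splits equivalent; smallest wins


def test_otsu_constant_raises():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full((5, 5), 7, np.uint8))


def test_otsu_domain_mask_restricts():
    img = np.zeros((10, 10), dtype=np.uint8)
    img[:5] = 200
    img[5:, :5] = 100
    mask = np.zeros((10, 10), bool)
    mask[5:] = True  # domain holds values {100, 0} only
    t = otsu_threshold(img, domain_mask=mask)
    assert t == bruteforce_otsu(img[mask])


def test_otsu_matches_bruteforce_random():
    rng = np.random.default_rng(3)
    for _ in range(30):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        assert otsu_threshold(img) == bruteforce_otsu(img)


def test_otsu_close_to_skimage():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(5)
    img = np.concatenate(
        [rng.normal(60, 8, 600), rng.normal(200, 10, 400)]
    ).clip(0, 255).astype(np.uint8).reshape(40, 25)
    assert abs(otsu_threshold(img) - threshold_otsu(img)) <= 1


# ------------------------------------------------------- mask refinement


def _refinement_frame():
    """Border-touching frame enclosing two blobs plus a speck, as Ī > tau."""
    comp = np.zeros((120, 120), dtype=np.uint8)
    comp[:10, :] = comp[-10:, :] = comp[:, :10] = comp[:, -10:] = 255  # frame
    comp[30:50, 30:50] = 255  # blob A, 400 px
    comp[60:80, 70:89] = 255  # blob B, 380 px
    comp[100:102, 55:60] = 255  # 10 px speck < min_area
    return comp


def test_make_lung_mask_keeps_only_interior_blobs():
    comp = _refinement_frame()
    lm = make_lung_mask(comp, tau_lung=128, min_area=50, dilation_radius=2)
    assert len(lm.components) == 2
    assert lm.mask[30:50, 30:50].all() and lm.mask[60:80, 70:89].all()
    assert not lm.mask[0, 0] and not lm.mask[5, 60]  # frame gone
    assert not lm.mask[101, 57]  # speck gone
    # dilation is extensive: no pre-dilation pixel lost
    lm0 = make_lung_mask(comp, tau_lung=128, min_area=50, dilation_radius=0)
    assert (lm.mask[lm0.mask]).all()


def test_make_lung_mask_single_component_goes_empty():
    comp = np.zeros((40, 40), dtype=np.uint8)
    comp[10:20, 10:20] = 255
    with pytest.warns(EmptySegmentationWarning):
        lm = make_lung_mask(comp, tau_lung=128)
    assert lm.is_empty


def test_make_lung_mask_fills_structure_holes():
    comp = _refinement_frame()
    comp[38:42, 38:42] = 0  # a bright inner structure punches a hole
    lm = make_lung_mask(comp, tau_lung=128, fill_holes=True)
    assert lm.mask[39:41, 39:41].all()
    lm_open = make_lung_mask(comp, tau_lung=128, fill_holes=False, dilation_radius=0)
    assert not lm_open.mask[40, 40]


# ------------------------------------------------------- full segmentation


def test_segment_lungs_recovers_phantom_mask():
    stack, truth = phantom(11)
    mask, lung = segment_lungs(stack[4])
    t = truth.lung_masks[4]
    jac = (mask.mask & t).sum() / (mask.mask | t).sum()
    assert jac >= 0.9
    assert (lung[~mask.mask] == 0).all()


def test_segment_lungs_all_black_slice():
    with pytest.warns(EmptySegmentationWarning):
        mask, lung = segment_lungs(np.zeros((64, 64), dtype=np.uint8))
    assert mask.is_empty and not lung.any()


def test_segmenter_reports_thresholds():
    stack, _ = phantom(11)
    seg = LungSegmenter().transform(stack[0])
    thr = seg.thresholds
    assert thr.lambda_source in ("second_minimum", "otsu_fallback")
    assert 0 <= thr.lambda_bg <= 255 and 0 <= thr.tau_lung <= 255
    # lambda must clear the dark-gray peaks but keep the bright structures
    assert 60 < thr.lambda_bg < 190


def test_median_filter_removes_salt_inside_lung():
    stack, truth = phantom(21, noise_sd=0.0, n_nodules=0, n_vessels=0)
    slc = stack[4]
    lung_pixels = np.argwhere(truth.lung_masks[4])
    r, c = lung_pixels[len(lung_pixels) // 2]
    pixels = slc.pixels.copy()
    pixels[r, c] = 255  # isolated salt pixel
    mask, lung = segment_lungs(pixels)
    assert lung[r, c] == 60  # restored to the neighborhood median


def test_sklearn_params_roundtrip():
    seg = LungSegmenter(kappa=7, dilation_radius=3)
    params = seg.get_params()
    assert params["kappa"] == 7
    clone = LungSegmenter(**params)
    assert clone.get_params() == params
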