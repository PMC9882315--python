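"""Segmentation recipe, Yen thresholding, and colocalization statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyphaquant import segcoloc, synthio
from hyphaquant.errors import DegenerateHistogramError, UndefinedStatisticError
from hyphaquant.segcoloc import (
    CooccurrenceRule,
    Punctum,
    SegmentationParams,
    estimate_background,
    intensity_ratio,
    manders,
    pearson,
    preprocess,
    score_cooccurrence,
    segment_puncta,
    yen_threshold,
)


def _pearson_oracle(a, b):
    """Direct-summation product-moment formula, no vectorized shortcuts."""
    a, b = a.ravel(), b.ravel()
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)


def _yen_oracle(hist, centers):
    """Exhaustive scan of the Yen maximum-correlation criterion."""
    p = hist / hist.sum()
    best, best_crit = None, -np.inf
    for t in range(len(p) - 1):
        P = sum(p[: t + 1])
        A = sum(x * x for x in p[: t + 1])
        B = sum(x * x for x in p[t + 1 :])
        if A <= 0 or B <= 0 or P <= 0 or P >= 1:
            continue
        crit = -np.log(A * B) + 2 * np.log(P * (1 - P))
        if crit > best_crit:
            best, best_crit = centers[t], crit
    return best


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def test_constant_image_preprocesses_to_zero():
    out = preprocess(np.full((40, 40), 500.0))
    assert np.allclose(out, 0.0, atol=1e-6)


def test_delta_spike_blur_matches_direct_kernel_convolution():
    img = np.zeros((21, 21))
    img[10, 10] = 1000.0
    params = SegmentationParams(rolling_radius_px=0)
    out = preprocess(img, params)
    # direct convolution with the sampled Gaussian kernel, kernel normalized
    yy, xx = np.mgrid[-10:11, -10:11].astype(float)
    kern = np.exp(-(yy**2 + xx**2) / 2.0)
    kern /= kern.sum()
    assert out[10, 10] == pytest.approx(1000.0 * kern[10, 10], rel=1e-3)


def test_rolling_ball_removes_tilted_background_and_keeps_spots():
    # the ball follows smooth gradients (removing them) but cannot enter
    # spot-sized peaks, which survive intact
    yy, xx = np.mgrid[0:80, 0:200].astype(float)
    img = 100.0 + 0.1 * xx  # 20-count tilt across the field
    img += 400.0 * np.exp(-((yy - 40) ** 2 + (xx - 100) ** 2) / (2 * 1.4**2))
    out = preprocess(img, SegmentationParams(blur_sigma_px=0, bg_presmooth_px=0))
    interior = out[10:70, 20:180].copy()
    interior[15:46, 65:116] = 0.0  # exclude the spot neighborhood
    assert interior.max() < 1.0  # background gone
    assert out[40, 100] == pytest.approx(400.0, rel=0.05)  # spot preserved


# ---------------------------------------------------------------------------
# Yen threshold
# ---------------------------------------------------------------------------


def test_yen_on_two_delta_peaks_lies_between_and_matches_oracle():
    img = np.concatenate([np.full(100, 10.0), np.full(100, 200.0)])
    thr = yen_threshold(img)
    assert 10.0 < thr < 200.0
    hist, edges = np.histogram(img, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    assert thr == _yen_oracle(hist, centers)


def test_yen_mirrored_histogram_mirrors_threshold():
    rng = np.random.default_rng(1)
    img = np.concatenate([rng.uniform(20, 30, 400), rng.uniform(150, 170, 100)])
    lo, hi = img.min(), img.max()
    thr = yen_threshold(img)
    thr_m = yen_threshold(lo + hi - img)
    # mirror symmetry holds up to the one-bin asymmetry of the cut convention
    bin_w = (hi - lo) / 256
    assert thr_m == pytest.approx(lo + hi - thr, abs=2.5 * bin_w)


def test_yen_matches_skimage_on_spot_image():
    rng = np.random.default_rng(2)
    img = rng.normal(100, 5, (64, 64))
    for y, x in [(10, 12), (40, 50), (25, 30)]:
        img[y - 1 : y + 2, x - 1 : x + 2] += 350.0
    from skimage.filters import threshold_yen

    assert yen_threshold(img) == pytest.approx(threshold_yen(img, nbins=256))


def test_yen_rejects_single_valued_image():
    with pytest.raises(DegenerateHistogramError):
        yen_threshold(np.full((8, 8), 3.0))


def test_yen_equals_exhaustive_oracle_on_random_histograms():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n_bins = rng.integers(8, 64)
        hist = rng.integers(0, 50, n_bins).astype(float)
        hist[rng.integers(0, n_bins)] += 200  # ensure structure
        if np.count_nonzero(hist) < 2:
            continue
        centers = np.arange(n_bins, dtype=float)
        assert segcoloc.yen_threshold_from_histogram(hist, centers) == _yen_oracle(
            hist, centers
        )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def test_blank_image_segments_to_no_puncta():
    puncta, mask = segment_puncta(np.full((32, 32), 100.0))
    assert puncta == [] and not mask.any()


def test_well_separated_synthetic_puncta_recovered_with_centroids():
    movie, truth = synthio.make_coloc_field(
        n_primary=12, frac_paired=0.0, n_unpaired_other=0,
        optics=synthio.OpticsParams(read_noise_sd=0.0, seed=1),
        apply_poisson=False, seed=11,
    )
    img = movie.frame(0, "488")
    puncta, _ = segment_puncta(img, channel="488")
    assert len(puncta) == 12
    # every ground-truth position has a centroid within 1 px
    hypha = synthio.straight_hypha(45.0, width_um=4.0, tip_yx_um=(4.0, 1.0))
    px = movie.pixel_size_um
    for tr in truth.tracks:
        pos = (hypha.point_at(tr.s_um[0]) + tr.lateral_um * hypha.normal_at(tr.s_um[0]))
        pos_px = pos / px
        dists = [np.hypot(*(np.array(p.centroid_px) - pos_px)) for p in puncta]
        assert min(dists) < 1.0


def test_unresolvable_pair_merges_into_one_punctum():
    img = np.zeros((40, 40))
    yy, xx = np.mgrid[0:40, 0:40].astype(float)
    for cx in (19.0, 21.5):  # separation below the PSF scale
        img += 400 * np.exp(-((yy - 20) ** 2 + (xx - cx) ** 2) / (2 * 1.4**2))
    puncta, _ = segment_puncta(img, SegmentationParams(rolling_radius_px=0))
    assert len(puncta) == 1


def test_segmentation_is_idempotent_on_the_cleared_image():
    movie, _ = synthio.make_coloc_field(
        n_primary=8, frac_paired=0.0, n_unpaired_other=0,
        optics=synthio.OpticsParams(read_noise_sd=0.0, seed=2),
        apply_poisson=False, seed=21,
    )
    img = movie.frame(0, "488")
    params = SegmentationParams()
    puncta, mask = segment_puncta(img, params, channel="488")
    cleared = np.where(mask, preprocess(img, params), 0.0)
    # re-segmenting the cleared image returns the same components
    again, mask2 = segment_puncta(
        cleared, SegmentationParams(blur_sigma_px=0, rolling_radius_px=0), channel="488"
    )
    assert len(again) == len(puncta)
    assert np.array_equal(mask2, mask)


# ---------------------------------------------------------------------------
# Pearson / Manders
# ---------------------------------------------------------------------------


def test_pearson_perfect_and_anti_correlation():
    rng = np.random.default_rng(4)
    img = rng.uniform(0, 100, (9, 9))
    assert pearson(img, img) == pytest.approx(1.0)
    assert pearson(img, 150.0 - img) == pytest.approx(-1.0)


def test_pearson_hand_computed_case():
    a = np.arange(1.0, 10.0).reshape(3, 3)
    b = 2.0 * a
    assert pearson(a, b) == pytest.approx(1.0)
    b[2, 2] = 10.0  # perturb one pixel
    assert pearson(a, b) == pytest.approx(_pearson_oracle(a, b), abs=1e-12)


def test_pearson_zero_variance_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        pearson(np.ones((4, 4)), np.random.default_rng(0).uniform(size=(4, 4)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_pearson_and_manders_match_direct_oracles_on_random_fields(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1000, (16, 16))
    b = rng.uniform(0, 1000, (16, 16))
    assert pearson(a, b) == pytest.approx(_pearson_oracle(a, b), abs=1e-10)
    mask_a = rng.random((16, 16)) < 0.4
    mask_b = rng.random((16, 16)) < 0.4
    if not (mask_a.any() and mask_b.any()):
        return
    m1, m2 = manders(a, b, mask_a, mask_b)
    both = mask_a & mask_b
    assert m1 == pytest.approx(a[both].sum() / a[mask_a].sum(), abs=1e-10)
    assert m2 == pytest.approx(b[both].sum() / b[mask_b].sum(), abs=1e-10)
    assert 0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0


def test_manders_subset_and_disjoint_masks():
    rng = np.random.default_rng(5)
    a = rng.uniform(1, 10, (8, 8))
    b = rng.uniform(1, 10, (8, 8))
    mask_a = np.zeros((8, 8), bool)
    mask_a[2:4, 2:4] = True
    mask_b = np.zeros((8, 8), bool)
    mask_b[1:6, 1:6] = True
    m1, _ = manders(a, b, mask_a, mask_b)
    assert m1 == pytest.approx(1.0)  # A's mask inside B's
    disjoint = np.zeros((8, 8), bool)
    disjoint[6:, 6:] = True
    assert manders(a, b, mask_a, disjoint) == (0.0, 0.0)


def test_manders_half_signal_overlap_gives_half():
    a = np.zeros((8, 8))
    mask_a = np.zeros((8, 8), bool)
    a[0, :4] = 5.0  # uniform signal over 4 pixels
    mask_a[0, :4] = True
    mask_b = np.zeros((8, 8), bool)
    mask_b[0, :2] = True  # covers half of A's signal
    m1, _ = manders(a, np.ones((8, 8)), mask_a, mask_b)
    assert m1 == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Co-occurrence rule
# ---------------------------------------------------------------------------


def _punctum(pid, coords, channel="488"):
    coords = np.asarray(coords)
    return Punctum(pid, channel, tuple(coords.mean(axis=0)), len(coords), 0.0, coords)


def test_identical_puncta_on_bright_channel_all_cooccur():
    coords = [(1, 1), (1, 2), (2, 1), (2, 2)]
    a = [_punctum(0, coords)]
    b = [_punctum(0, coords, "561")]
    img_b = np.full((5, 5), 100.0)
    frac, flags = score_cooccurrence(a, b, img_b, background_b=10.0)
    assert frac == 1.0 and flags == [True]


def test_flat_opposite_channel_scores_zero():
    coords = [(1, 1), (1, 2), (2, 1), (2, 2)]
    a = [_punctum(0, coords)]
    b = [_punctum(0, coords, "561")]
    img_b = np.full((5, 5), 50.0)
    frac, _ = score_cooccurrence(a, b, img_b, background_b=50.0)
    assert frac == 0.0  # 50 < 1.1 x 50


def test_overlap_threshold_is_strict_at_half():
    a = [_punctum(0, [(0, c) for c in range(10)])]  # 10-px punctum on row 0
    img_b = np.full((3, 12), 100.0)

    def b_with_overlap(k):
        # 10-px opposite punctum sharing exactly k pixels with `a`
        coords = [(0, c) for c in range(10 - k, 10)] + [(1, c) for c in range(10 - k)]
        return [_punctum(0, coords, "561")]

    frac40, _ = score_cooccurrence(a, b_with_overlap(4), img_b, background_b=10.0)
    frac60, _ = score_cooccurrence(a, b_with_overlap(6), img_b, background_b=10.0)
    # exactly 50% must NOT count (strict inequality as printed)
    frac50, _ = score_cooccurrence(a, b_with_overlap(5), img_b, background_b=10.0)
    assert (frac40, frac50, frac60) == (0.0, 0.0, 1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 50.0))
def test_raising_opposite_channel_brightness_never_unscores(seed, boost):
    rng = np.random.default_rng(seed)
    img_b = rng.uniform(0, 100, (12, 12))
    coords = [(y, x) for y in range(3, 6) for x in range(3, 6)]
    a = [_punctum(0, coords)]
    b = [_punctum(0, coords[:5], "561")]
    _, flags_lo = score_cooccurrence(a, b, img_b, background_b=30.0)
    _, flags_hi = score_cooccurrence(a, b, img_b + boost, background_b=30.0)
    assert flags_hi[0] >= flags_lo[0]


def test_empty_reference_puncta_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        score_cooccurrence([], [], np.ones((4, 4)), 1.0)


# ---------------------------------------------------------------------------
# Intensity ratio and background estimate
# ---------------------------------------------------------------------------


def test_intensity_ratio_cases():
    rng = np.random.default_rng(6)
    a = rng.uniform(1, 100, (10, 10))
    roi = [(2, 3), (4, 5), (6, 7), (1, 1), (8, 2)]
    assert intensity_ratio(roi, a, a) == pytest.approx(1.0)
    assert intensity_ratio(roi, 2 * a, a) == pytest.approx(2.0)
    vals_a = [a[y, x] for y, x in roi]
    b = np.full((10, 10), 4.0)
    assert intensity_ratio(roi, a, b) == pytest.approx(np.mean(vals_a) / 4.0)
    with pytest.raises(UndefinedStatisticError):
        intensity_ratio(roi, a, np.zeros((10, 10)))


def test_background_estimate_excludes_dilated_mask():
    from scipy.ndimage import binary_dilation

    img = np.full((20, 20), 7.0)
    mask = np.zeros((20, 20), bool)
    mask[5:8, 5:8] = True
    img[4:9, 4:9] = 1000.0  # spill-over just around the mask
    bg = estimate_background(img, mask, dilation_px=2)
    outside = ~binary_dilation(mask, iterations=2)
    assert bg == np.median(img[outside])
    assert bg < 1000.0
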