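"""Histogram construction and the ten binarization methods."""

import numpy as np
import pytest

from mgmfseg.thresholding import (
    DegenerateHistogramError,
    Histogram,
    LocalParams,
    METHODS,
    NoConcavityError,
    concavity,
    kapur,
    make_histogram,
    moments,
    niblack,
    otsu,
    pal_entropy,
    rats,
    ridler_calvard,
    sauvola,
    segment,
    white_rohrer,
)
from conftest import random_histograms


def hist_from_counts(counts):
    return Histogram(counts=np.asarray(counts, dtype=np.int64), vmin=0.0, vmax=1.0)


def delta_hist(pairs):
    counts = np.zeros(256, dtype=np.int64)
    for bin_, n in pairs:
        counts[bin_] = n
    return hist_from_counts(counts)


# ---------------------------------------------------------------- oracles

def scan_oracle(counts, objective):
    """Exhaustive 256-candidate scan of a stated objective; smallest-t ties."""
    best_t, best = None, -np.inf
    for t in range(255):
        val = objective(np.asarray(counts, dtype=float), t)
        if val is not None and val > best:
            best_t, best = t, val
    return best_t


def otsu_objective(counts, t):
    total = counts.sum()
    w0, w1 = counts[: t + 1].sum(), counts[t + 1 :].sum()
    if w0 == 0 or w1 == 0:
        return None
    levels = np.arange(256.0)
    mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / w0
    mu1 = (counts[t + 1 :] * levels[t + 1 :]).sum() / w1
    return (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2


def kapur_objective(counts, t):
    p = counts / counts.sum()
    w0, w1 = p[: t + 1].sum(), p[t + 1 :].sum()
    if w0 <= 0 or w1 <= 0:
        return None
    h = 0.0
    for q, w in ((p[: t + 1], w0), (p[t + 1 :], w1)):
        q = q[q > 0] / w
        h += -(q * np.log(q)).sum()
    return h


def pal_objective(counts, t):
    p = counts / counts.sum()
    w0, w1 = p[: t + 1].sum(), p[t + 1 :].sum()
    if w0 <= 0 or w1 <= 0:
        return None
    h = 0.0
    for q, w in ((p[: t + 1], w0), (p[t + 1 :], w1)):
        q = q[q > 0] / w
        h += (q * np.exp(1 - q)).sum()
    return h


def concavity_oracle(counts):
    """Upper hull via qhull (independent of the implementation's monotone chain)."""
    from scipy.spatial import ConvexHull

    n = len(counts)
    pts = np.column_stack([np.arange(n, dtype=float), np.asarray(counts, dtype=float)])
    # append a point far below so the lower hull never touches the histogram
    pts = np.vstack([pts, [n / 2.0, -1e12]])
    hull_idx = sorted(v for v in ConvexHull(pts).vertices if v < n)
    hx = pts[hull_idx, 0]
    hy = pts[hull_idx, 1]
    hull = np.interp(np.arange(n), hx, hy)
    diff = hull - counts
    if np.all(diff <= 1e-9):
        return None
    padded = np.concatenate([[-np.inf], diff, [-np.inf]])
    local = (diff >= padded[:-2]) & (diff >= padded[2:]) & (diff > 1e-9)
    cand = np.flatnonzero(local)
    return int(cand[np.argmax(diff[cand])])


# ---------------------------------------------------------------- histogram

class TestHistogram:
    def test_minmax_endpoints(self):
        h = make_histogram(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert h.counts[0] == 2 and h.counts[255] == 2
        assert h.counts.sum() == 4

    def test_count_conservation(self, rng):
        img = rng.random((37, 53))
        assert make_histogram(img).total == img.size

    def test_uniform_image_fills_bins_uniformly(self):
        rng = np.random.default_rng(99)
        img = rng.random(10**6)
        h = make_histogram(img)
        # endpoint bins receive half-width mass under round-half-up binning
        interior = h.counts[1:-1]
        expected = img.size / 255.0
        chi2 = float(((interior - expected) ** 2 / expected).sum())
        from scipy.stats import chi2 as chi2_dist

        assert chi2 < chi2_dist.ppf(0.999, df=len(interior) - 1)

    def test_constant_image_degenerate(self):
        h = make_histogram(np.full((4, 4), 0.3))
        assert h.degenerate and h.counts[0] == 16


# ---------------------------------------------------------------- global methods

class TestGlobalExamples:
    def test_otsu_two_deltas(self):
        assert otsu(delta_hist([(10, 50), (200, 50)])) == 10

    def test_otsu_symmetric_bimodal(self):
        """Equal Gaussian modes at 80 and 180 (sigma 10) threshold near 130.

        Counts follow the analytic mixture density (scaled), so the valley is
        smooth and strictly positive and the between-class-variance maximizer
        is unique; sampled histograms with an empty valley would instead hit
        the smallest-t tie rule at the valley's left edge.
        """
        from scipy.stats import norm

        levels = np.arange(256)
        density = norm.pdf(levels, 80, 10) + norm.pdf(levels, 180, 10)
        h = hist_from_counts(np.round(density * 1e12).astype(np.int64))
        assert abs(otsu(h) - 130) <= 2

    def test_otsu_count_scaling_invariant(self):
        h = delta_hist([(30, 7), (90, 11), (200, 5)])
        doubled = hist_from_counts(h.counts * 2)
        assert otsu(h) == otsu(doubled)

    def test_ridler_two_deltas(self):
        assert ridler_calvard(delta_hist([(10, 50), (200, 50)])) == 105

    def test_ridler_binary_endpoints(self):
        assert ridler_calvard(delta_hist([(0, 40), (255, 40)])) == 128

    def test_kapur_uniform(self):
        assert kapur(hist_from_counts(np.full(256, 10))) == 127

    def test_kapur_two_deltas_smallest_separator(self):
        assert kapur(delta_hist([(37, 5), (200, 9)])) == 37

    def test_pal_uniform(self):
        assert pal_entropy(hist_from_counts(np.full(256, 10))) == 127

    def test_pal_two_deltas_smallest_separator(self):
        assert pal_entropy(delta_hist([(37, 5), (200, 9)])) == 37

    def test_moments_two_deltas(self):
        assert moments(delta_hist([(10, 50), (200, 50)])) == 10

    def test_moments_symmetric_split(self):
        counts = np.zeros(256, dtype=int)
        for offset, n in ((10, 40), (30, 25), (55, 10)):
            counts[128 - offset] = n
            counts[128 + offset] = n
        h = hist_from_counts(counts)
        t = moments(h)
        p0 = counts[: t + 1].sum() / counts.sum()
        assert p0 == pytest.approx(0.5, abs=0.02)

    def test_concavity_valley(self):
        """Three-segment bimodal histogram: the threshold lands inside the valley.

        Triangular modes keep the outer slopes on the hull; the hull-histogram
        gap is maximal over the chord spanning the valley between the peaks.
        """
        counts = np.zeros(256, dtype=int)
        counts[20:61] = np.interp(np.arange(20, 61), [20, 40, 60], [0, 120, 40])
        counts[60:181] = np.interp(np.arange(60, 181), [60, 120, 180], [40, 8, 100])
        counts[180:241] = np.interp(np.arange(180, 241), [180, 200, 240], [100, 100, 0])
        t = concavity(hist_from_counts(counts))
        assert 60 < t < 180

    def test_concavity_concave_histogram_errors(self):
        """A concave (single triangular mode) histogram coincides with its hull."""
        i = np.arange(256)
        counts = 10 + 2 * np.minimum(i, 255 - i)  # exact-integer tent
        with pytest.raises(NoConcavityError):
            concavity(hist_from_counts(counts))

    def test_concavity_vertical_shift_invariant(self):
        counts = np.zeros(256, dtype=int)
        counts[20:60] = 80
        counts[60:100] = 5
        counts[100:140] = 60
        h = hist_from_counts(counts)
        shifted = hist_from_counts(counts + 13)
        assert concavity(h) == concavity(shifted)

    @pytest.mark.parametrize("method", [otsu, ridler_calvard, kapur, pal_entropy, moments])
    def test_degenerate_histogram_rejected(self, method):
        with pytest.raises(DegenerateHistogramError):
            method(delta_hist([(7, 100)]))


class TestOracleEquivalence:
    """Each optimizing method must equal an exhaustive scan of its objective."""

    @pytest.mark.parametrize(
        "method,objective",
        [(otsu, otsu_objective), (kapur, kapur_objective), (pal_entropy, pal_objective)],
        ids=["otsu", "kapur", "pal"],
    )
    def test_scan_oracle(self, method, objective):
        for h in random_histograms(100, seed=2024):
            assert method(h) == scan_oracle(h.counts, objective)

    def test_concavity_oracle(self):
        for h in random_histograms(25, seed=77):
            expected = concavity_oracle(h.counts)
            if expected is None:
                with pytest.raises(NoConcavityError):
                    concavity(h)
            else:
                assert concavity(h) == expected

    def test_moments_residuals(self):
        """Implied binary image preserves the first three moments to 1e-6 relative."""
        for h in random_histograms(100, seed=31, min_occupied=3):
            counts = h.counts.astype(float)
            p = counts / counts.sum()
            levels = np.arange(256.0)
            m1, m2, m3 = (p @ levels**k for k in (1, 2, 3))
            cd = m2 - m1**2
            if cd <= 1e-9:
                continue
            c0 = (m1 * m3 - m2 * m2) / cd
            c1 = (m1 * m2 - m3) / cd
            disc = c1 * c1 - 4 * c0
            if disc < 0:
                continue
            z0, z1 = 0.5 * (-c1 - np.sqrt(disc)), 0.5 * (-c1 + np.sqrt(disc))
            p0 = (z1 - m1) / (z1 - z0)
            if not (0 < p0 < 1):
                continue
            t = moments(h)
            # threshold must place the cumulative fraction astride p0
            cum = np.cumsum(p)
            below = cum[t - 1] if t > 0 else 0.0
            assert below <= p0 + 1e-9 <= cum[t] + 1e-6
            # and the two-level reconstruction reproduces the moments
            for k in (1, 2, 3):
                recon = p0 * z0**k + (1 - p0) * z1**k
                assert recon == pytest.approx((p @ levels**k), rel=1e-6, abs=1e-6)

    def test_ridler_terminates_fast(self):
        for h in random_histograms(100, seed=55):
            t = ridler_calvard(h)  # internal repeat detection bounds this by 256
            assert 0 <= t <= 255


class TestRats:
    def test_step_image(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        assert rats(img) == pytest.approx(0.5, abs=1e-12)

    def test_affine_covariance(self, rng):
        img = rng.random((20, 20))
        t = rats(img)
        assert rats(2.5 * img + 0.3) == pytest.approx(2.5 * t + 0.3, abs=1e-9)

    def test_within_range(self, rng):
        img = rng.random((30, 30))
        assert img.min() <= rats(img) <= img.max()

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            rats(np.full((5, 5), 0.4))


class TestLocalMethods:
    def test_niblack_constant_all_background(self):
        mask = niblack(np.full((20, 20), 0.5), LocalParams(window=5, k=-0.2))
        assert not mask.any()

    def test_niblack_k_zero_is_local_mean(self, rng):
        img = rng.random((20, 20))
        mask = niblack(img, LocalParams(window=5, k=0.0))
        from scipy.ndimage import uniform_filter

        np.testing.assert_array_equal(mask, img > uniform_filter(img, 5, mode="reflect"))

    def test_niblack_bright_disc(self):
        img = np.zeros((64, 64))
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 <= 6**2
        img[disc] = 1.0
        mask = niblack(img, LocalParams(window=31, k=-0.2))
        assert mask[disc].all()
        # beyond disc radius + window corner reach (6 + 15*sqrt(2)) the window
        # sees only zeros, so mean = std = 0 and strict '>' keeps background
        far = (rr - 32) ** 2 + (cc - 32) ** 2 >= 29**2
        assert not mask[far].any()

    def test_sauvola_pivot_identity(self, rng):
        """When s(p) = R the threshold reduces to the local mean."""
        img = rng.random((20, 20))
        from scipy.ndimage import uniform_filter

        params = LocalParams(window=5, k=0.5, R=0.5)
        mean, = (uniform_filter(img, 5, mode="reflect"),)
        sq = uniform_filter(img * img, 5, mode="reflect")
        std = np.sqrt(np.maximum(sq - mean**2, 0))
        mask = sauvola(img, params)
        expected = img > mean * (1 + params.k * (std / params.R - 1))
        np.testing.assert_array_equal(mask, expected)

    def test_sauvola_constant_positive_all_foreground(self):
        mask = sauvola(np.full((16, 16), 0.6), LocalParams(window=5, k=0.5, R=0.5))
        assert mask.all()  # c > c * (1 - k) for c, k > 0

    def test_white_rohrer_constant_all_background(self):
        mask = white_rohrer(np.full((16, 16), 0.6), LocalParams(window=5, bias=1.0))
        assert not mask.any()

    def test_white_rohrer_single_bright_pixel(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        mask = white_rohrer(img, LocalParams(window=5, bias=1.0))
        assert mask[7, 7]

    def test_white_rohrer_bias_monotone(self, rng):
        img = rng.random((20, 20))
        m1 = white_rohrer(img, LocalParams(window=5, bias=1.0))
        m2 = white_rohrer(img, LocalParams(window=5, bias=1.5))
        assert np.all(m2[m1])  # foreground at bias 1 stays foreground at 1.5

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            niblack(np.zeros((5, 5)), LocalParams(window=7))


class TestSegmentDispatch:
    def test_all_methods_dispatch(self, rng):
        img = rng.random((32, 32))
        for method in METHODS:
            mask = segment(img, method)
            assert mask.dtype == bool and mask.shape == img.shape

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            segment(rng.random((8, 8)), "magic")

    def test_otsu_mask_matches_bruteforce_threshold(self, rng):
        scores = np.concatenate(
            [rng.normal(0.2, 0.05, 600), rng.normal(0.8, 0.05, 400)]
        ).reshape(40, 25)
        mask = segment(scores, "otsu")
        h = make_histogram(scores)
        t = scan_oracle(h.counts, otsu_objective)
        np.testing.assert_array_equal(mask, h.bin_of(scores) > t)

    def test_all_zero_response_all_background(self):
        mask = segment(np.zeros((10, 10)), "otsu")
        assert not mask.any()

    def test_affine_rescale_leaves_global_masks_unchanged(self, rng):
        img = rng.random((24, 24))
        for method in ("otsu", "kapur", "moments", "ridler_calvard"):
            np.testing.assert_array_equal(
                segment(img, method), segment(3.0 * img + 1.0, method)
            )

    def test_otsu_agrees_with_skimage_on_smooth_data(self, rng):
        """Independent cross-check: the selected cutoff matches skimage's within a bin."""
        from skimage.filters import threshold_otsu

        scores = np.concatenate(
            [rng.normal(0.25, 0.07, 3000), rng.normal(0.75, 0.07, 2000)]
        )
        h = make_histogram(scores)
        t = otsu(h)
        our_cut = h.vmin + t / 255.0 * (h.vmax - h.vmin)
        sk_cut = threshold_otsu(scores, nbins=256)
        assert abs(our_cut - sk_cut) <= (h.vmax - h.vmin) / 128
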