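"""Threshold algorithms against brute-force oracles and closed forms."""

import numpy as np
import pytest

from octavasc.exceptions import ConvergenceError, LayerError, NoContrastError, OctavascError
from octavasc.images import EnFaceAngiogram
from octavasc.thresholding import (
    binarize_layer,
    li_threshold,
    otsu_threshold,
    phansalkar_binarize,
)

from conftest import make_angiogram


# ---------------------------------------------------------------- oracles

def otsu_bruteforce(pixels, n_bins=256):
    """Exhaustive between-class-variance scan over all histogram levels."""
    px = pixels.ravel()
    hist, edges = np.histogram(px, bins=n_bins, range=(px.min(), px.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_t = -1.0, None
    total = hist.sum()
    for i in range(n_bins - 1):
        w0 = hist[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (hist[i + 1 :] * centers[i + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_t = v, centers[i]
    return best_t


def li_cross_entropy(pixels, t):
    """Li's cross-entropy criterion for threshold t (positive intensities)."""
    px = pixels.ravel()
    below, above = px[px <= t], px[px > t]
    if below.size == 0 or above.size == 0:
        return np.inf
    return -(below.sum() * np.log(below.mean()) + above.sum() * np.log(above.mean()))


def phansalkar_naive(pixels, radius, k=0.25, r=0.5, p=2.0, q=10.0):
    """Double-loop windowed-formula oracle with mirror padding."""
    padded = np.pad(pixels, radius, mode="reflect")
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    fp = (yy**2 + xx**2) <= radius**2
    out = np.empty_like(pixels)
    H, W = pixels.shape
    for i in range(H):
        for j in range(W):
            win = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1][fp]
            mu, sd = win.mean(), win.std()
            out[i, j] = mu * (1 + p * np.exp(-q * mu) + k * (sd / r - 1))
    return out


# ---------------------------------------------------------------- Otsu

class TestOtsu:
    def test_two_level_separation(self):
        px = np.array([[0.2] * 32, [0.8] * 32] * 32, dtype=float)
        t = otsu_threshold(make_angiogram(px))
        assert 0.2 < t < 0.8
        assert (px > t).any() and (px <= t).any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.uniform(0.05, 0.95, (64, 64))
        assert otsu_threshold(make_angiogram(px)) == pytest.approx(
            otsu_bruteforce(px), abs=1e-12
        )

    def test_shift_and_scale_equivariance(self, rng):
        px = rng.uniform(0.1, 0.5, (64, 64))
        t = otsu_threshold(make_angiogram(px))
        bin_width = (px.max() - px.min()) / 256
        shifted = otsu_threshold(make_angiogram(px + 0.1))
        assert shifted == pytest.approx(t + 0.1, abs=bin_width)
        scaled = otsu_threshold(make_angiogram(1.5 * px + 0.05))
        assert scaled == pytest.approx(1.5 * t + 0.05, abs=1.5 * bin_width)

    def test_constant_image_rejected(self):
        with pytest.raises(NoContrastError):
            otsu_threshold(make_angiogram(np.full((8, 8), 0.5)))

    def test_threshold_strictly_inside_range(self, rng):
        for _ in range(10):
            px = rng.uniform(0, 1, (32, 32))
            t = otsu_threshold(make_angiogram(px))
            assert px.min() < t < px.max()

    def test_permutation_invariant(self, rng):
        px = rng.uniform(0.05, 0.95, (32, 32))
        t1 = otsu_threshold(make_angiogram(px))
        shuffled = rng.permutation(px.ravel()).reshape(px.shape)
        assert otsu_threshold(make_angiogram(shuffled)) == t1


# ---------------------------------------------------------------- Li

class TestLi:
    @pytest.mark.parametrize("seed", range(20))
    def test_attains_grid_search_minimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        px = rng.uniform(0.05, 0.95, (64, 64))
        t = li_threshold(make_angiogram(px))
        grid = np.linspace(px.min(), px.max(), 1002)[1:-1]
        objective = np.array([li_cross_entropy(px, g) for g in grid])
        step = grid[1] - grid[0]
        best = grid[np.argmin(objective)]
        assert li_cross_entropy(px, t) <= objective.min() + 1e-9 or abs(t - best) <= step

    def test_two_level_image(self):
        px = np.array([[0.2] * 32, [0.8] * 32] * 32, dtype=float)
        assert 0.2 < li_threshold(make_angiogram(px)) < 0.8

    def test_zero_iterations_is_nonconvergence(self, random_image):
        with pytest.raises(ConvergenceError) as err:
            li_threshold(random_image, max_iter=0)
        assert err.value.last_iterate is not None

    def test_constant_image_rejected(self):
        with pytest.raises(NoContrastError):
            li_threshold(make_angiogram(np.full((8, 8), 0.3)))

    def test_scale_equivariance(self, rng):
        px = rng.uniform(0.1, 0.5, (64, 64))
        t = li_threshold(make_angiogram(px))
        assert li_threshold(make_angiogram(1.8 * px)) == pytest.approx(1.8 * t, rel=1e-4)

    def test_permutation_invariant(self, rng):
        px = rng.uniform(0.05, 0.95, (32, 32))
        t1 = li_threshold(make_angiogram(px))
        shuffled = rng.permutation(px.ravel()).reshape(px.shape)
        assert li_threshold(make_angiogram(shuffled)) == pytest.approx(t1, abs=1e-9)

    def test_agrees_with_skimage_reference(self, rng):
        # skimage internally shifts the image to a zero minimum before
        # iterating (cross-entropy is origin-dependent), so compare on a
        # min-zero image where the conventions coincide
        from skimage.filters import threshold_li

        px = rng.uniform(0.05, 0.95, (64, 64))
        px -= px.min()
        assert li_threshold(make_angiogram(px)) == pytest.approx(
            threshold_li(px), abs=1e-3
        )


# ---------------------------------------------------------------- Phansalkar

class TestPhansalkar:
    def test_constant_image_closed_form(self):
        # t = 0.5 * (1 + 2*exp(-5) - 0.25) with defaults
        img = make_angiogram(np.full((40, 40), 0.5), layer="choriocapillaris")
        expected_t = 0.5 * (1 + 2 * np.exp(-5.0) - 0.25)
        assert expected_t == pytest.approx(0.38174, abs=5e-4)
        out = phansalkar_binarize(img, radius_px=5, polarity="bright_fg")
        assert out.pixels.all()  # 0.5 > 0.38 everywhere
        dark = phansalkar_binarize(img, radius_px=5, polarity="dark_fg")
        assert not dark.pixels.any()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_windowed_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        px = rng.uniform(0, 1, (16, 16))
        img = make_angiogram(px, layer="choriocapillaris")
        out = phansalkar_binarize(img, radius_px=3, polarity="bright_fg")
        t_oracle = phansalkar_naive(px, 3)
        np.testing.assert_array_equal(out.pixels, px > t_oracle)

    def test_dark_disk_detected_as_dark_foreground(self):
        px = np.full((64, 64), 0.9)
        yy, xx = np.mgrid[:64, :64]
        disk_mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2
        px[disk_mask] = 0.1
        out = phansalkar_binarize(
            make_angiogram(px, layer="choriocapillaris"), radius_px=6, polarity="dark_fg"
        )
        interior = (yy - 32) ** 2 + (xx - 32) ** 2 <= 6**2
        assert out.pixels[interior].all()
        far = (yy - 32) ** 2 + (xx - 32) ** 2 >= 20**2
        assert not out.pixels[far].any()

    def test_not_permutation_invariant(self, rng):
        px = np.linspace(0, 1, 256).reshape(16, 16)
        img = make_angiogram(px, layer="choriocapillaris")
        base = phansalkar_binarize(img, radius_px=3).pixels
        shuffled = rng.permutation(px.ravel()).reshape(16, 16)
        other = phansalkar_binarize(
            make_angiogram(shuffled, layer="choriocapillaris"), radius_px=3
        ).pixels
        assert base.sum() != other.sum() or not np.array_equal(base, other)

    def test_oversized_radius_rejected(self):
        img = make_angiogram(np.random.default_rng(0).uniform(0, 1, (16, 16)))
        with pytest.raises(OctavascError):
            phansalkar_binarize(img, radius_px=10)


# ---------------------------------------------------------------- dispatch

class TestBinarizeLayer:
    @pytest.mark.parametrize(
        "layer,expected",
        [("superficial", "li"), ("deep", "otsu"), ("choriocapillaris", "phansalkar")],
    )
    def test_layer_algorithm_assignment(self, rng, layer, expected):
        img = make_angiogram(rng.uniform(0.05, 0.95, (48, 48)), layer=layer)
        out = binarize_layer(img)
        assert out.provenance["algorithm"] == expected
        if expected == "phansalkar":
            assert out.provenance["polarity"] == "bright_fg"
        assert out.shape == img.shape

    def test_unknown_layer_rejected(self, random_image):
        random_image.layer = "ganglion"  # bypass constructor validation
        with pytest.raises(LayerError):
            binarize_layer(random_image)

    def test_requires_angiogram(self, rng):
        with pytest.raises(OctavascError):
            binarize_layer(rng.uniform(0, 1, (8, 8)))
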