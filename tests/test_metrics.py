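"""Evaluation metrics: RMSE, ratio image, cross-covariance, histogram, D_B."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smartscan import metrics, phantom


class TestRmse:
    def test_identical_cubes(self, rng):
        a = rng.random((4, 4, 8))
        assert metrics.rmse(a, a) == 0.0

    def test_unit_offset(self):
        assert metrics.rmse(np.ones((3, 3, 5)), np.zeros((3, 3, 5))) == 1.0

    def test_hand_expanded_toy_value(self):
        out = np.array([[[1.0, 3.0]], [[2.0, 2.0]]])
        ref = np.full((2, 1, 2), 2.0)
        assert metrics.rmse(out, ref) == pytest.approx(np.sqrt(0.5))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics.rmse(np.zeros((2, 2, 3)), np.zeros((2, 2, 4)))

    @given(st.integers(0, 10_000))
    def test_decomposes_as_mean_of_per_pixel_mse(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random((3, 4, 6)), r.random((3, 4, 6))
        per_pixel = np.mean((a - b) ** 2, axis=-1)
        assert metrics.rmse(a, b) ** 2 == pytest.approx(per_pixel.mean())


class TestRatioImage:
    def test_constant_cube_constant_ratio(self):
        wn = phantom.wavenumber_axis(64)
        cube = np.zeros((2, 2, 64))
        cube[..., np.argmin(np.abs(wn - 960))] = 4.0
        cube[..., np.argmin(np.abs(wn - 1450))] = 2.0
        ri = metrics.ratio_image(cube, wn)
        assert np.all(ri.mask)
        np.testing.assert_allclose(ri.values, 2.0)

    def test_swapping_bands_gives_reciprocal(self, small_cube, small_scene):
        wn = small_scene.wavenumber_axis
        a = metrics.ratio_image(small_cube, wn, 960, 1450)
        b = metrics.ratio_image(small_cube, wn, 1450, 960)
        m = a.mask & b.mask
        np.testing.assert_allclose(a.values[m], 1.0 / b.values[m], rtol=1e-9)

    def test_monotone_in_mineral_fraction(self):
        """Ratio strictly increases along a 1-D sweep of mineral abundance."""
        ems = phantom.default_endmembers(2, L=128)
        E = np.stack([e.spectrum for e in ems])
        a = np.linspace(0.1, 0.9, 9)
        cube = (np.outer(a, E[0]) + np.outer(1 - a, E[1]))[None, ...]
        ri = metrics.ratio_image(cube, phantom.wavenumber_axis(128))
        assert np.all(np.diff(ri.values[0]) > 0)

    def test_near_zero_denominator_masked(self):
        wn = phantom.wavenumber_axis(64)
        cube = np.ones((2, 2, 64))
        i2 = np.argmin(np.abs(wn - 1450))
        cube[0, 0, i2] = 0.0
        ri = metrics.ratio_image(cube, wn)
        assert not ri.mask[0, 0]
        assert ri.mask[1, 1]

    def test_wavenumber_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            metrics.ratio_image(np.ones((2, 2, 8)), np.linspace(400, 800, 8))


class TestCrossCovariance:
    def test_self_and_anti_correlation(self, rng):
        a = rng.random((10, 10))
        assert metrics.cross_covariance(a, a) == pytest.approx(1.0)
        assert metrics.cross_covariance(a, -a) == pytest.approx(-1.0)

    def test_positive_affine_invariance(self, rng):
        a = rng.random((10, 10))
        assert metrics.cross_covariance(a, 3 * a + 7) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        cs = [
            metrics.cross_covariance(
                np.random.default_rng(2 * s).random((100, 100)),
                np.random.default_rng(2 * s + 1).random((100, 100)),
            )
            for s in range(50)
        ]
        assert abs(np.mean(cs)) < 0.05

    @given(st.integers(0, 10_000))
    def test_bounded_by_one(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random((6, 6)), r.random((6, 6))
        assert abs(metrics.cross_covariance(a, b)) <= 1.0 + 1e-12

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            metrics.cross_covariance(np.ones((4, 4)), rng.random((4, 4)))

    def test_symmetry(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert metrics.cross_covariance(a, b) == pytest.approx(
            metrics.cross_covariance(b, a)
        )


class TestHistogram:
    def test_point_mass(self):
        d = metrics.histogram([2.5] * 10, delta=0.5)
        assert d.densities.sum() * d.delta == pytest.approx(1.0)
        assert d.densities.max() == pytest.approx(1.0 / 0.5)

    def test_hand_computed_example(self):
        d = metrics.histogram(
            [0.1, 0.1, 0.3, 0.5], delta=0.2, value_range=(0.0, 0.6)
        )
        np.testing.assert_allclose(d.bin_centers, [0.1, 0.3, 0.5], atol=1e-12)
        np.testing.assert_allclose(d.densities, [2.5, 1.25, 1.25])

    def test_uniform_law_of_large_numbers(self):
        v = np.random.default_rng(0).random(100_000)
        d = metrics.histogram(v, delta=0.05, value_range=(0.0, 1.0))
        np.testing.assert_allclose(d.densities, 1.0, atol=0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metrics.histogram([])

    @given(st.integers(0, 10_000))
    def test_unit_mass_always(self, seed):
        v = np.random.default_rng(seed).normal(size=200)
        d = metrics.histogram(v)
        assert d.delta * d.densities.sum() == pytest.approx(1.0, abs=1e-9)


class TestBhattacharyya:
    def test_identical_distributions_give_zero(self, rng):
        v = rng.normal(size=500)
        f = metrics.histogram(v, delta=0.25, value_range=(-4, 4))
        assert metrics.bhattacharyya(f, f) == 0.0

    def test_disjoint_point_masses_give_infinity(self):
        f = metrics.histogram([0.05], delta=0.1, value_range=(0, 1))
        g = metrics.histogram([0.95], delta=0.1, value_range=(0, 1))
        assert metrics.bhattacharyya(f, g) == np.inf

    def test_equal_variance_gaussians_closed_form(self):
        """D_B between N(0,1) and N(1,1) is mu^2 / (8 sigma^2) = 0.125."""
        delta = 0.01
        centers = np.arange(-6, 7, delta) + delta / 2
        def gauss_dist(mu):
            pdf = np.exp(-0.5 * (centers - mu) ** 2) / np.sqrt(2 * np.pi)
            pdf = pdf / (pdf.sum() * delta)
            return metrics.Distribution(centers, delta, pdf, n=1)
        db = metrics.bhattacharyya(gauss_dist(0.0), gauss_dist(1.0))
        assert db == pytest.approx(0.125, abs=1e-3)

    def test_symmetry(self, rng):
        a = metrics.histogram(rng.normal(0, 1, 400), delta=0.2, value_range=(-5, 5))
        b = metrics.histogram(rng.normal(1, 1, 400), delta=0.2, value_range=(-5, 5))
        assert metrics.bhattacharyya(a, b) == pytest.approx(
            metrics.bhattacharyya(b, a)
        )

    def test_mismatched_bin_width_rejected(self):
        f = metrics.histogram([0.5], delta=0.1, value_range=(0, 1))
        g = metrics.histogram([0.5], delta=0.2, value_range=(0, 1))
        with pytest.raises(ValueError):
            metrics.bhattacharyya(f, g)

    def test_from_samples_shared_grid(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(0.5, 1, 2000)
        db = metrics.bhattacharyya_from_samples(a, b)
        assert 0 < db < 0.2  # true value ~0.031 plus finite-sample bias


class TestSmoothedDensity:
    def test_preserves_unit_mass(self, rng):
        d = metrics.histogram(rng.normal(size=300))
        sm = metrics.smoothed_density(d, bandwidth_bins=2.0)
        assert sm.delta * sm.densities.sum() == pytest.approx(1.0, abs=1e-9)
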