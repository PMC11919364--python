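"""Phasor transform and convex-hull essential-spectra selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smartscan import acquisition, essential, phantom
from smartscan.essential import PhasorCloud, SpectralMatrix


def naive_phasor(spectrum, r):
    """O(L) summation oracle for the pinned DFT convention."""
    L = len(spectrum)
    lam = np.arange(L)
    c = np.sum(spectrum * np.exp(-2j * np.pi * (r - 1) * lam / L))
    l1 = np.sum(np.abs(spectrum))
    return c.real / l1, c.imag / l1


def brute_force_hull(points):
    """Brute-force hull-vertex oracle, independent of qhull: point i is a
    vertex iff it is not a convex combination of the other points (checked
    by a small feasibility linear program per point)."""
    from scipy.optimize import linprog

    pts = np.asarray(points)
    n = len(pts)
    out = set()
    for i in range(n):
        others = np.delete(np.arange(n), i)
        A_eq = np.vstack([pts[others].T, np.ones(len(others))])
        b_eq = np.append(pts[i], 1.0)
        res = linprog(np.zeros(len(others)), A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * len(others), method="highs")
        if not res.success:
            out.add(i)
    return out


class TestPhasorTransform:
    def test_constant_spectrum_maps_to_origin(self):
        cloud = essential.phasor_transform(np.ones((3, 64)), harmonic_r=2)
        np.testing.assert_allclose(cloud.g, 0.0, atol=1e-12)
        np.testing.assert_allclose(cloud.q, 0.0, atol=1e-12)

    def test_cosine_matches_naive_dft_oracle(self):
        L = 64
        lam = np.arange(L)
        s = 1 + np.cos(2 * np.pi * lam / L)
        cloud = essential.phasor_transform(s[None, :], harmonic_r=2)
        g0, q0 = naive_phasor(s, 2)
        assert cloud.g[0] == pytest.approx(g0, abs=1e-9)
        assert cloud.q[0] == pytest.approx(q0, abs=1e-9)
        assert cloud.g[0] > 0
        assert cloud.q[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("r", [2, 3, 7])
    def test_random_spectra_match_naive_dft(self, rng, r):
        spectra = rng.random((10, 48))
        cloud = essential.phasor_transform(spectra, harmonic_r=r)
        for p in range(10):
            g0, q0 = naive_phasor(spectra[p], r)
            assert cloud.g[p] == pytest.approx(g0, abs=1e-9)
            assert cloud.q[p] == pytest.approx(q0, abs=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        spectra = rng.random((5, 32))
        a = essential.phasor_transform(spectra)
        b = essential.phasor_transform(c * spectra)
        np.testing.assert_allclose(a.g, b.g, atol=1e-9)
        np.testing.assert_allclose(a.q, b.q, atol=1e-9)

    def test_zero_norm_spectrum_rejected_with_position(self):
        sm = SpectralMatrix(
            np.vstack([np.ones(16), np.zeros(16)]), [(0, 0), (3, 4)]
        )
        with pytest.raises(ValueError, match=r"\[3, 4\]"):
            essential.phasor_transform(sm)

    def test_dc_harmonic_rejected(self):
        with pytest.raises(ValueError):
            essential.phasor_transform(np.ones((2, 16)), harmonic_r=1)


class TestEssentialSelect:
    def test_triangle_is_its_own_hull(self):
        cloud = PhasorCloud(g=[0, 1, 0], q=[0, 0, 1], harmonic_r=2)
        es = essential.essential_select(cloud)
        assert set(es.indices) == {0, 1, 2}

    def test_square_excludes_interior_point(self):
        cloud = PhasorCloud(
            g=[0, 1, 1, 0, 0.5], q=[0, 0, 1, 1, 0.5], harmonic_r=2
        )
        es = essential.essential_select(cloud)
        assert set(es.indices) == {0, 1, 2, 3}

    def test_triangle_corners_always_selected(self, rng):
        corners = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        w = rng.dirichlet(np.ones(3), size=200)
        inner = w @ corners
        pts = np.vstack([corners, inner])
        cloud = PhasorCloud(g=pts[:, 0], q=pts[:, 1], harmonic_r=2)
        es = essential.essential_select(cloud)
        assert {0, 1, 2} <= set(es.indices)
        assert es.n_essential >= 3

    @pytest.mark.parametrize("n", [5, 12, 30])
    def test_matches_brute_force_hull(self, rng, n):
        pts = rng.normal(size=(n, 2))
        cloud = PhasorCloud(g=pts[:, 0], q=pts[:, 1], harmonic_r=2)
        es = essential.essential_select(cloud)
        assert set(es.indices) == brute_force_hull(pts)

    def test_all_points_inside_selected_hull(self, rng):
        from scipy.optimize import linprog

        pts = rng.normal(size=(40, 2))
        cloud = PhasorCloud(g=pts[:, 0], q=pts[:, 1], harmonic_r=2)
        es = essential.essential_select(cloud)
        hull_pts = pts[es.indices]
        for p in pts:
            A_eq = np.vstack([hull_pts.T, np.ones(len(hull_pts))])
            res = linprog(
                np.zeros(len(hull_pts)), A_eq=A_eq, b_eq=np.append(p, 1.0),
                bounds=[(0, None)] * len(hull_pts), method="highs",
            )
            assert res.success  # p is a convex combination of the vertices

    def test_coincident_cloud_gives_single_point(self):
        cloud = PhasorCloud(g=[0.3] * 5, q=[0.7] * 5, harmonic_r=2)
        es = essential.essential_select(cloud)
        assert list(es.indices) == [0]

    def test_collinear_cloud_gives_two_extremes(self):
        t = np.array([0.5, 0.1, 0.9, 0.4])
        cloud = PhasorCloud(g=t, q=2 * t, harmonic_r=2)
        es = essential.essential_select(cloud)
        assert set(es.indices) == {1, 2}

    def test_permutation_equivariance(self, rng):
        spectra = rng.random((20, 32))
        perm = rng.permutation(20)
        a = essential.essential_select(essential.phasor_transform(spectra))
        b = essential.essential_select(essential.phasor_transform(spectra[perm]))
        assert set(perm[b.indices]) == set(a.indices)

    def test_scale_invariance_of_selection(self, rng):
        spectra = rng.random((20, 32))
        a = essential.essential_select(essential.phasor_transform(spectra))
        b = essential.essential_select(essential.phasor_transform(5.5 * spectra))
        assert np.array_equal(a.indices, b.indices)

    def test_pure_endmembers_recovered_on_noiseless_phantom(self):
        """K=3 noiseless mixtures: every endmember appearing pure in the
        sample set must be a hull vertex, so K <= H and the essential set
        spans the endmember spectra."""
        ems = phantom.default_endmembers(3, L=128)
        E = np.stack([e.spectrum for e in ems])
        rng = np.random.default_rng(4)
        w = rng.dirichlet(np.ones(3), size=60)
        spectra = np.vstack([E, w @ E])  # pure spectra first
        es = essential.essential_select(essential.phasor_transform(spectra), spectra)
        assert {0, 1, 2} <= set(es.indices)


def test_essential_table_layout(rng):
    spectra = rng.random((12, 32))
    pos = np.column_stack([np.arange(12), np.arange(12) * 2])
    sm = SpectralMatrix(spectra, pos)
    cloud = essential.phasor_transform(sm)
    es = essential.essential_select(cloud, sm)
    df = essential.essential_table(es, cloud)
    assert list(df.columns) == ["index", "x", "y", "g", "q"]
    assert len(df) == es.n_essential
    np.testing.assert_allclose(df["g"].to_numpy(), cloud.g[es.indices])


class TestRescan:
    def test_shape_and_order_contract(self, small_cube, calibrated_noise):
        es = essential.EssentialSet(
            indices=[0, 1], positions=np.array([(2, 3), (10, 11)])
        )
        sm = essential.rescan_essential(es, small_cube, 5000, calibrated_noise, 0)
        assert sm.spectra.shape == (2, 128)
        assert sm.snr_tag == "high"
        assert np.array_equal(sm.positions, es.positions)

    def test_high_dwell_rescan_raises_snr(self, small_cube, calibrated_noise):
        pos = np.array([(x, y) for x in range(0, 32, 4) for y in range(0, 32, 4)])
        es = essential.EssentialSet(indices=np.arange(len(pos)), positions=pos)
        w = acquisition.sg_window_for_bands(128)
        wins = 0
        for s in range(20):
            low = acquisition.acquire(small_cube, pos, 100, calibrated_noise, s)
            high = essential.rescan_essential(
                es, small_cube, 5000, calibrated_noise, 1000 + s
            )
            if acquisition.estimate_snr(high.spectra, w) > acquisition.estimate_snr(low, w):
                wins += 1
        assert wins == 20
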