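"""Baseline correction, derivatives, binning, band selection and I/O."""

import numpy as np
import pytest

from mirmsi.hyperspectral import (
    HyperCube,
    PlaneImage,
    PreprocessConfig,
    SpectralAxis,
    als_baseline,
    bin_spatial,
    load_cube,
    load_plane,
    save_cube,
    save_plane,
    select_bands,
    spectral_derivative,
    to_absorbance,
    to_transmittance,
)


def _cube_from_spectrum(spectrum, shape=(4, 5), mode="absorbance"):
    axis = SpectralAxis.default()
    v = np.tile(np.asarray(spectrum, float), shape + (1,))
    return HyperCube(v, axis, pixel_size_um=4.66, mode=mode)


def _reference_als(y, lam, p, n_iter):
    """Independent dense-matrix ALS (textbook formulation) as oracle."""
    m = len(y)
    D = np.diff(np.eye(m), 2, axis=0)
    w = np.ones(m)
    for _ in range(n_iter):
        W = np.diag(w)
        z = np.linalg.solve(W + lam * D.T @ D, w * y)
        w = np.where(y > z, p, 1 - p)
    return z


class TestAlsBaseline:
    def test_constant_spectrum(self):
        c = 3.7
        z = als_baseline(np.full(100, c))
        assert np.max(np.abs(z - c)) < 1e-6 * abs(c) + 1e-9

    def test_linear_ramp(self):
        # second-difference penalty vanishes on linear functions
        y = np.linspace(0.0, 2.0, 150)
        z = als_baseline(y)
        assert np.max(np.abs(z - y)) < 1e-3 * np.ptp(y)

    def test_suppresses_positive_peak(self):
        x = np.linspace(0, 1, 200)
        y = np.exp(-0.5 * ((x - 0.5) / 0.02) ** 2)
        z = als_baseline(y)
        assert np.max(np.abs(z[(x > 0.45) & (x < 0.55)])) < 0.05

    def test_matches_dense_reference(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 80)
        y = 0.3 + 0.5 * x + np.exp(-0.5 * ((x - 0.6) / 0.03) ** 2)
        y += rng.normal(0, 0.005, x.size)
        mine = als_baseline(y, lam=1e4, p=0.01, n_iter=10)
        ref = _reference_als(y, lam=1e4, p=0.01, n_iter=10)
        assert np.allclose(mine, ref, atol=1e-8)

    def test_additive_constant_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 120)
        assert np.allclose(als_baseline(y + 5.0), als_baseline(y) + 5.0,
                           atol=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            als_baseline(np.array([1.0, 2.0]))


class TestDerivative:
    def test_sg_exact_for_quadratic(self):
        axis = SpectralAxis.default()
        cube = _cube_from_spectrum(axis.wavenumbers**2)
        d2 = spectral_derivative(cube, 2, "savitzky_golay")
        interior = d2.values[0, 0, 3:-3]
        assert np.allclose(interior, 2.0, atol=1e-6)
        assert d2.mode == "derivative2"

    def test_finite_difference_matches_closed_form(self):
        axis = SpectralAxis.default()
        wn = axis.wavenumbers
        cube = _cube_from_spectrum(np.sin(wn / 50.0))
        d1 = spectral_derivative(cube, 1, "finite_difference")
        expected = np.cos(wn / 50.0) / 50.0
        h = axis.spacing
        err = np.abs(d1.values[0, 0, 1:-1] - expected[1:-1])
        assert err.max() < (h / 50.0) ** 2  # O(h^2) central differences

    def test_second_derivative_minimum_at_band_center(self):
        axis = SpectralAxis.default()
        wn = axis.wavenumbers
        band = np.exp(-0.5 * ((wn - 1466.0) / 12.0) ** 2)
        cube = _cube_from_spectrum(band)
        d2 = spectral_derivative(cube, 2, "savitzky_golay")
        assert wn[np.argmin(d2.values[0, 0])] == 1466.0

    def test_affine_spectrum_has_zero_second_derivative(self):
        axis = SpectralAxis.default()
        cube = _cube_from_spectrum(0.3 * axis.wavenumbers + 2.0)
        d2 = spectral_derivative(cube, 2, "finite_difference")
        assert np.max(np.abs(d2.values)) < 1e-9

    def test_bad_order(self):
        cube = _cube_from_spectrum(np.ones(213))
        with pytest.raises(ValueError):
            spectral_derivative(cube, 3)

    def test_sg_window_too_wide(self):
        axis = SpectralAxis(np.arange(950.0, 970.0, 4.0))
        cube = HyperCube(np.ones((2, 2, len(axis))), axis, 4.66)
        with pytest.raises(ValueError):
            spectral_derivative(cube, 2, "savitzky_golay",
                                PreprocessConfig(sg_window=7))


class TestAbsorbance:
    def test_known_values_and_roundtrip(self):
        cube = _cube_from_spectrum(np.full(213, 0.1), mode="transmittance")
        a = to_absorbance(cube)
        assert np.allclose(a.values, 1.0)
        t1 = _cube_from_spectrum(np.ones(213), mode="transmittance")
        assert np.allclose(to_absorbance(t1).values, 0.0)
        rng = np.random.default_rng(2)
        x = _cube_from_spectrum(rng.uniform(0.05, 1.0, 213),
                                mode="transmittance")
        rt = to_transmittance(to_absorbance(x))
        assert np.allclose(rt.values, x.values, atol=1e-12)

    def test_nonpositive_clamped_with_warning(self):
        vals = np.full(213, 0.5)
        vals[0] = -0.1
        cube = _cube_from_spectrum(vals, mode="transmittance")
        with pytest.warns(UserWarning, match="clamping"):
            a = to_absorbance(cube)
        assert np.isfinite(a.values).all()


class TestBinning:
    def test_constant_cube(self):
        cube = _cube_from_spectrum(np.ones(213), shape=(6, 8))
        out = bin_spatial(cube, 2)
        assert out.shape == (3, 4, 213)
        assert np.allclose(out.values, 1.0)
        assert out.pixel_size_um == pytest.approx(2 * 4.66)

    def test_block_mean(self):
        axis = SpectralAxis(np.array([1000.0, 1004.0]))
        v = np.zeros((2, 2, 2))
        v[:, :, 0] = [[1, 2], [3, 4]]
        v[:, :, 1] = [[10, 20], [30, 40]]
        cube = HyperCube(v, axis, 1.0)
        out = bin_spatial(cube, 2)
        assert out.values[0, 0, 0] == pytest.approx(2.5)
        assert out.values[0, 0, 1] == pytest.approx(25.0)

    def test_mean_conservation(self):
        rng = np.random.default_rng(3)
        cube = _cube_from_spectrum(np.ones(213), shape=(8, 8))
        cube.values[:] = rng.normal(size=cube.values.shape)
        out = bin_spatial(cube, 4)
        assert out.values.mean() == pytest.approx(cube.values.mean(), abs=1e-12)

    def test_factor_too_large(self):
        cube = _cube_from_spectrum(np.ones(213), shape=(3, 3))
        with pytest.raises(ValueError):
            bin_spatial(cube, 5)


class TestBandSelection:
    def test_exact_grid_point(self):
        cube = _cube_from_spectrum(np.arange(213, dtype=float))
        out = select_bands(cube, [1466.0])
        assert out.axis.wavenumbers.tolist() == [1466.0]
        assert (1466.0 - 950.0) / 4.0 == 129  # 1466 is on the grid

    def test_nearest_within_tolerance(self):
        cube = _cube_from_spectrum(np.arange(213, dtype=float))
        out = select_bands(cube, [1467.0], tolerance=2.0)
        assert out.axis.wavenumbers.tolist() == [1466.0]

    def test_out_of_range_names_offender(self):
        cube = _cube_from_spectrum(np.arange(213, dtype=float))
        with pytest.raises(ValueError, match="900"):
            select_bands(cube, [900.0])


class TestIO:
    def test_cube_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        cube = _cube_from_spectrum(rng.normal(size=213), shape=(3, 4))
        p = tmp_path / "cube.h5"
        save_cube(cube, p)
        back = load_cube(p)
        assert np.array_equal(back.values, cube.values)
        assert np.array_equal(back.axis.wavenumbers, cube.axis.wavenumbers)
        assert back.pixel_size_um == cube.pixel_size_um
        assert back.mode == cube.mode

    def test_plane_roundtrip(self, tmp_path):
        plane = PlaneImage(np.random.default_rng(5).normal(size=(6, 7)),
                           pixel_size_um=2.3, wavenumber=1656.0)
        p = tmp_path / "plane.tif"
        save_plane(plane, p)
        back = load_plane(p)
        assert np.allclose(back.values, plane.values, atol=1e-6)
        assert back.wavenumber == 1656.0

    def test_plane_uint8_export(self, tmp_path):
        plane = PlaneImage(np.linspace(0, 1, 64).reshape(8, 8),
                           pixel_size_um=4.66)
        p = tmp_path / "plane8.tif"
        save_plane(plane, p, dtype=np.uint8)
        back = load_plane(p)
        assert back.values.min() == 0 and back.values.max() == 255


def test_axis_validation():
    with pytest.raises(ValueError):
        SpectralAxis(np.array([]))
    with pytest.raises(ValueError):
        SpectralAxis(np.array([1000.0, 999.0]))
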