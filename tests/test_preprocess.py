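import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import binom

from leafspec import (
    SpectraSet,
    fod_sweep,
    fod_transform,
    gl_coefficients,
    savgol_smooth,
    trim_edges,
)
from leafspec.preprocess import DEFAULT_ORDERS, FODConfig


def make_set(values, start=400):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    wl = np.arange(start, start + values.shape[1])
    ids = [f"s{i}" for i in range(values.shape[0])]
    return SpectraSet(ids, wl, values)


def gamma_weights(v, m):
    """Independent closed-form oracle: w_k = (−1)^k · C(v, k)."""
    k = np.arange(m + 1)
    return (-1.0) ** k * binom(v, k)


class TestTrim:
    def test_default_window_keeps_2001_bands(self):
        s = make_set(np.zeros((1, 2151)), start=350)
        trimmed = trim_edges(s)
        assert trimmed.n_bands == 2001
        assert trimmed.wavelengths[0] == 400 and trimmed.wavelengths[-1] == 2400

    def test_degenerate_single_band(self):
        s = make_set(np.zeros((1, 2151)), start=350)
        assert trim_edges(s, 550, 550).n_bands == 1

    def test_empty_intersection_errors(self):
        s = make_set(np.zeros((1, 10)), start=400)
        with pytest.raises(ValueError):
            trim_edges(s, 5000, 6000)


class TestSavgol:
    def test_polynomial_reproduced_exactly(self):
        wl = np.arange(400, 430, dtype=float)
        row = 0.3 + 0.001 * (wl - 400) - 2e-5 * (wl - 400) ** 2
        s = make_set(row)
        out = savgol_smooth(s, window=9, polyorder=2)
        np.testing.assert_allclose(out.reflectance[0], row, atol=1e-9)

    def test_five_point_window_matches_normal_equations(self):
        # explicit least-squares oracle on a 5-point row, degree 2, centre point
        row = np.array([0.2, 0.35, 0.3, 0.45, 0.5])
        s = make_set(row)
        out = savgol_smooth(s, window=5, polyorder=2)
        x = np.arange(-2, 3, dtype=float)
        A = np.vander(x, 3, increasing=True)
        coef, *_ = np.linalg.lstsq(A, row, rcond=None)
        assert out.reflectance[0, 2] == pytest.approx(coef[0], abs=1e-12)

    def test_constant_row_unchanged(self):
        s = make_set(np.full(20, 0.42))
        out = savgol_smooth(s)
        np.testing.assert_allclose(out.reflectance, 0.42, atol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(8, 2), (5, 5), (51, 2)])
    def test_invalid_parameters_rejected(self, window, polyorder):
        s = make_set(np.zeros(20))
        with pytest.raises(ValueError):
            savgol_smooth(s, window=window, polyorder=polyorder)


class TestGLCoefficients:
    def test_integer_orders_terminate_in_difference_stencils(self):
        np.testing.assert_allclose(gl_coefficients(1.0, 4), [1, -1, 0, 0, 0], atol=1e-15)
        np.testing.assert_allclose(gl_coefficients(2.0, 4), [1, -2, 1, 0, 0], atol=1e-15)

    def test_half_order_values(self):
        np.testing.assert_allclose(
            gl_coefficients(0.5, 3), [1, -0.5, -0.125, -0.0625], atol=1e-12
        )

    @given(st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=30)
    def test_fractional_weights_shrink_and_sum_toward_zero(self, v):
        w = gl_coefficients(v, 200)
        mags = np.abs(w[1:])
        assert np.all(np.diff(mags) < 0)  # strictly decreasing |w_k| for k>=1
        partial = np.abs(np.cumsum(w))
        assert partial[-1] < partial[1]
        assert partial[-1] == pytest.approx(abs((-1.0) ** 200 * binom(v - 1, 200)), rel=1e-9)


class TestFODTransform:
    def test_order_zero_is_identity_with_full_mask(self, tiny_spectra):
        res = fod_transform(tiny_spectra, 0.0)
        np.testing.assert_array_equal(res.spectra.reflectance, tiny_spectra.reflectance)
        assert res.valid_mask.all()

    def test_first_order_is_backward_difference(self):
        res = fod_transform(make_set([1.0, 3.0, 6.0, 10.0]), 1.0)
        np.testing.assert_allclose(res.spectra.reflectance[0, 1:], [2, 3, 4], atol=1e-12)
        np.testing.assert_array_equal(res.valid_mask, [False, True, True, True])

    def test_half_order_matches_direct_gamma_summation(self):
        row = np.linspace(0.1, 1.0, 10)
        res = fod_transform(make_set(row), 0.5)
        w = gamma_weights(0.5, 9)
        expected = [np.dot(w[: j + 1], row[j::-1]) for j in range(10)]
        np.testing.assert_allclose(res.spectra.reflectance[0], expected, atol=1e-9)

    @pytest.mark.parametrize("order", [0.3, 0.8, 1.0, 1.7])
    def test_linearity_in_the_input(self, order):
        rng = np.random.default_rng(2)
        Xa, Xb = rng.random((2, 3, 30))
        a, b = 1.7, -0.4
        fa = fod_transform(make_set(Xa), order).spectra.reflectance
        fb = fod_transform(make_set(Xb), order).spectra.reflectance
        fab = fod_transform(make_set(a * Xa + b * Xb), order).spectra.reflectance
        np.testing.assert_allclose(fab, a * fa + b * fb, atol=1e-9)

    def test_memory_truncation_limits_history(self):
        row = np.ones(8)
        res = fod_transform(make_set(row), 0.5, FODConfig(memory=2))
        w = gamma_weights(0.5, 2)
        np.testing.assert_allclose(res.spectra.reflectance[0, 2:], w.sum(), atol=1e-12)

    def test_non_unit_grid_rejected(self):
        s = SpectraSet(["a"], np.array([400, 402, 404]), np.zeros((1, 3)))
        with pytest.raises(ValueError, match="resample"):
            fod_transform(s, 0.5)


class TestSweep:
    def test_default_sweep_yields_eleven_orders(self, tiny_spectra):
        results = fod_sweep(tiny_spectra)
        assert len(results) == 11
        assert [r.order for r in results] == list(DEFAULT_ORDERS)

    def test_singleton_sweep_is_passthrough(self, tiny_spectra):
        (res,) = fod_sweep(tiny_spectra, orders=[0.0])
        np.testing.assert_array_equal(res.spectra.reflectance, tiny_spectra.reflectance)
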