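"""Spline machinery: basis functions, interpolation, smoothing, penalty."""

import json

import numpy as np
import pytest
from scipy.integrate import quad

from odeinput.splines import (InputSpline, bspline_basis, curvature_matrix,
                              curvature_penalty, interpolating_spline,
                              penalty_root, select_lambda, smoothing_spline,
                              weighted_rss)


def cox_de_boor(kv, i, p, t):
    """Independent textbook recursion (naive, exponential) as oracle."""
    if p == 0:
        if kv[i] <= t < kv[i + 1]:
            return 1.0
        # half-open convention; close the last non-empty interval at the top
        if t == kv[-1] and kv[i] < kv[i + 1] == kv[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if kv[i + p] > kv[i]:
        left = (t - kv[i]) / (kv[i + p] - kv[i]) * cox_de_boor(kv, i, p - 1, t)
    right = 0.0
    if kv[i + p + 1] > kv[i + 1]:
        right = (kv[i + p + 1] - t) / (kv[i + p + 1] - kv[i + 1]) * cox_de_boor(kv, i + 1, p - 1, t)
    return left + right


class TestBsplineBasis:
    def test_degree0_is_indicator(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        b = bspline_basis(knots, 0, 1.5)
        assert b.tolist() == [0.0, 1.0, 0.0]

    @pytest.mark.parametrize("degree", [1, 2, 3])
    @pytest.mark.parametrize("t", [0.0, 0.37, 1.0, 2.9, 5.0])
    def test_partition_of_unity(self, degree, t):
        knots = np.array([0.0, 1.0, 2.5, 3.0, 5.0])
        assert bspline_basis(knots, degree, t).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("t", [0.0, 1.0, 1.7, 2.0, 3.3, 4.0])
    def test_matches_cox_de_boor_oracle(self, t):
        knots = np.linspace(0.0, 4.0, 5)
        p = 3
        kv = np.concatenate([[knots[0]] * p, knots, [knots[-1]] * p])
        ours = bspline_basis(knots, p, t)
        oracle = [cox_de_boor(kv, i, p, t) for i in range(len(kv) - p - 1)]
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_outside_support_raises(self):
        with pytest.raises(ValueError, match="outside"):
            bspline_basis(np.array([0.0, 1.0, 2.0]), 3, 2.5)


class TestInterpolation:
    def test_reproduces_straight_line(self):
        sp = interpolating_spline([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert sp(0.5) == pytest.approx(0.5, abs=1e-12)

    def test_interpolates_exactly(self, rng):
        t = np.sort(rng.uniform(0, 10, 8))
        y = rng.normal(size=8)
        sp = interpolating_spline(t, y)
        assert np.max(np.abs(sp(t) - y)) < 1e-10

    def test_natural_boundary_curvature_vanishes(self, rng):
        t = np.linspace(0, 5, 6)
        sp = interpolating_spline(t, rng.normal(size=6))
        assert abs(sp.second_derivative(t[0])) < 1e-9
        assert abs(sp.second_derivative(t[-1])) < 1e-9

    def test_matches_dense_linear_system_oracle(self, rng):
        # classic natural-spline construction: solve the dense tridiagonal
        # system for the knot curvatures m_i, then evaluate piecewise
        t = np.sort(rng.uniform(0, 10, 5))
        y = rng.normal(size=5)
        h = np.diff(t)
        n = len(t)
        a = np.zeros((n, n))
        b = np.zeros(n)
        a[0, 0] = a[-1, -1] = 1.0
        for i in range(1, n - 1):
            a[i, i - 1] = h[i - 1] / 6
            a[i, i] = (h[i - 1] + h[i]) / 3
            a[i, i + 1] = h[i] / 6
            b[i] = (y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1]
        m = np.linalg.solve(a, b)

        def oracle(x):
            j = np.clip(np.searchsorted(t, x) - 1, 0, n - 2)
            hj = h[j]
            u, v = (t[j + 1] - x) / hj, (x - t[j]) / hj
            return (u * y[j] + v * y[j + 1]
                    + ((u**3 - u) * m[j] + (v**3 - v) * m[j + 1]) * hj**2 / 6)

        sp = interpolating_spline(t, y)
        xs = np.linspace(t[0], t[-1], 40)
        np.testing.assert_allclose(sp(xs), [oracle(x) for x in xs], atol=1e-9)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            interpolating_spline([0.0, 1.0, 1.0, 2.0], [0, 1, 1, 2])


class TestSmoothing:
    @pytest.fixture()
    def data(self, rng):
        t = np.linspace(0, 10, 9)
        y = np.sin(t / 2) + rng.normal(0, 0.3, t.size)
        s = np.full(t.size, 0.3)
        return t, y, s

    def test_lambda_zero_is_interpolation(self, data):
        t, y, s = data
        sp = smoothing_spline(t, y, s, lam=0.0)
        np.testing.assert_allclose(sp.control_points, y, atol=1e-12)

    def test_lambda_inf_is_weighted_linear_fit(self, data):
        t, y, s = data
        sp = smoothing_spline(t, y, s, lam=1e12)
        w = 1.0 / s**2
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        line = X @ beta
        np.testing.assert_allclose(sp.control_points, line, rtol=1e-6)

    def test_rss_nondecreasing_penalty_nonincreasing_in_lambda(self, data):
        t, y, s = data
        lams = np.logspace(-4, 4, 9)
        rss = []
        pen = []
        for lam in lams:
            sp = smoothing_spline(t, y, s, lam=lam)
            rss.append(weighted_rss(sp, t, y, s))
            pen.append(curvature_penalty(sp))
        assert np.all(np.diff(rss) >= -1e-9)
        assert np.all(np.diff(pen) <= 1e-9)

    def test_negative_lambda_rejected(self, data):
        t, y, s = data
        with pytest.raises(ValueError):
            smoothing_spline(t, y, s, lam=-1.0)


class TestSelectLambda:
    def test_straight_line_selects_grid_maximum(self):
        t = np.linspace(0, 10, 8)
        y = 2.0 + 0.5 * t
        lam = select_lambda(t, y, np.full(t.size, 0.1))
        assert lam == pytest.approx(1e6, rel=1e-9)

    def test_discrepancy_definition_on_grid(self, rng):
        from scipy.stats import chi2
        t = np.linspace(0, 50, 12)
        y = np.log10(100 * np.exp(-((t - 25) ** 2) / (2 * 7.5**2)) + 1e-3)
        y = y + rng.normal(0, 0.3, t.size)
        s = np.full(t.size, 0.3)
        grid = np.logspace(-6, 6, 25)
        lam = select_lambda(t, y, s, grid=grid)
        bound = chi2.ppf(0.5, df=t.size)
        assert weighted_rss(smoothing_spline(t, y, s, lam=lam), t, y, s) <= bound
        bigger = grid[grid > lam]
        if bigger.size:
            nxt = bigger[0]
            assert weighted_rss(smoothing_spline(t, y, s, lam=nxt), t, y, s) > bound

    def test_larger_sigmas_allow_more_smoothing(self, rng):
        t = np.linspace(0, 50, 12)
        y = np.sin(t / 8) + rng.normal(0, 0.2, t.size)
        s = np.full(t.size, 0.2)
        assert select_lambda(t, y, 2 * s) >= select_lambda(t, y, s)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_lambda([0, 1, 2], [0, 1, 2], [1, 1, 1])


class TestEvaluation:
    def test_log_scale_strictly_positive(self, rng):
        sp = InputSpline(np.linspace(0, 5, 6), rng.normal(0, 3, 6), log_scale=True)
        ts = np.linspace(0, 5, 200)
        assert np.all(sp(ts) > 0)

    def test_constant_control_points_give_constant_power(self):
        sp = InputSpline(np.linspace(0, 5, 6), np.full(6, 1.3), log_scale=True)
        np.testing.assert_allclose(sp(np.linspace(0, 5, 50)), 10**1.3, rtol=1e-12)

    def test_knot_values_reproduced_without_log(self, rng):
        t = np.linspace(0, 5, 7)
        y = rng.normal(size=7)
        sp = interpolating_spline(t, y)
        np.testing.assert_allclose(sp(t), y, atol=1e-12)

    def test_constant_extrapolation_outside_window(self, rng):
        t = np.linspace(0, 5, 6)
        y = rng.normal(size=6)
        sp = interpolating_spline(t, y)
        assert sp(-3.0) == pytest.approx(y[0])
        assert sp(8.0) == pytest.approx(y[-1])


class TestCurvaturePenalty:
    def test_collinear_data_zero_penalty(self):
        sp = interpolating_spline([0.0, 1.0, 3.0, 4.0], [1.0, 2.0, 4.0, 5.0])
        assert curvature_penalty(sp) == pytest.approx(0.0, abs=1e-18)

    def test_matches_adaptive_quadrature(self):
        t = np.linspace(0, 4, 5)
        sp = interpolating_spline(t, [0.0, 1.0, 4.0, 1.0, 0.0])
        val, _ = quad(lambda x: sp.second_derivative(x) ** 2, 0, 4, limit=200)
        assert curvature_penalty(sp) == pytest.approx(val, rel=1e-8)

    def test_quadratic_scaling(self, rng):
        t = np.linspace(0, 6, 7)
        y = rng.normal(size=7)
        base = curvature_penalty(interpolating_spline(t, y))
        scaled = curvature_penalty(interpolating_spline(t, 3.0 * y))
        assert scaled == pytest.approx(9.0 * base, rel=1e-10)

    def test_penalty_matrix_agrees_with_closed_form(self, rng):
        t = np.sort(rng.uniform(0, 10, 8))
        v = rng.normal(size=8)
        k = curvature_matrix(t)
        sp = interpolating_spline(t, v)
        assert v @ k @ v == pytest.approx(curvature_penalty(sp), rel=1e-9)

    def test_penalty_root_factorizes_matrix(self, rng):
        t = np.linspace(0, 10, 7)
        l = penalty_root(t)
        np.testing.assert_allclose(l @ l.T, curvature_matrix(t), atol=1e-9)
        assert l.shape == (7, 5)  # two-dimensional null space: straight lines


def test_serialization_roundtrip(rng):
    sp = InputSpline(np.linspace(0, 5, 6), rng.normal(size=6), lam=0.7, log_scale=True)
    sp2 = InputSpline.from_json(sp.to_json())
    np.testing.assert_array_equal(sp2.knots, sp.knots)
    np.testing.assert_array_equal(sp2.control_points, sp.control_points)
    assert sp2.lam == sp.lam and sp2.log_scale is True
    assert json.loads(sp.to_json())["degree"] == 3
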