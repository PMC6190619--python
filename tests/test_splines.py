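"""Restricted cubic spline basis, knot placement, and the two-spline survival model."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as hst

import extrasurv as xs
from extrasurv.splines import rcs_basis, rcs_basis_deriv


def _truncated_power_oracle(x, knots):
    """Brute-force restricted-cubic evaluation, written independently of rcs_basis."""
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), np.asarray(x, float)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        term = np.zeros_like(x)
        for i, xi in enumerate(x):
            term[i] = (
                max(xi - kj, 0.0) ** 3
                - lam * max(xi - kmin, 0.0) ** 3
                - (1 - lam) * max(xi - kmax, 0.0) ** 3
            )
        cols.append(term)
    return np.column_stack(cols)


class TestBasis:
    def test_no_internal_knots_degenerates_to_line(self):
        x = np.linspace(-2, 4, 9)
        B = rcs_basis(x, [0.0, 1.0])
        np.testing.assert_array_equal(B, np.column_stack([np.ones_like(x), x]))

    def test_linear_tails_beyond_boundary_knots(self):
        knots = np.log([0.3, 1.0, 14.0, 40.0])
        h = 0.05
        for x0 in (knots[-1] + 0.5, knots[0] - 0.5):
            x = np.array([x0 - h, x0, x0 + h])
            B = rcs_basis(x, knots)
            second_diff = B[0] - 2 * B[1] + B[2]
            np.testing.assert_allclose(second_diff, 0.0, atol=1e-8)

    def test_matches_truncated_power_oracle_between_knots(self):
        knots = np.array([-1.0, 0.2, 1.0, 2.5])
        x = np.linspace(-1.5, 3.0, 23)
        np.testing.assert_allclose(rcs_basis(x, knots), _truncated_power_oracle(x, knots), rtol=1e-12)

    def test_continuous_second_derivative_at_knots(self):
        knots = np.array([-1.0, 0.2, 1.0, 2.5])
        for k in knots[1:-1]:
            h = 1e-4
            left = (rcs_basis(np.array([k - 2 * h]), knots) - 2 * rcs_basis(np.array([k - h]), knots) + rcs_basis(np.array([k]), knots)) / h**2
            right = (rcs_basis(np.array([k]), knots) - 2 * rcs_basis(np.array([k + h]), knots) + rcs_basis(np.array([k + 2 * h]), knots)) / h**2
            np.testing.assert_allclose(left, right, atol=2e-3)

    def test_derivative_matches_finite_differences(self):
        knots = np.array([-1.0, 0.2, 1.0, 2.5])
        x = np.linspace(-1.4, 3.0, 17)
        eps = 1e-6
        fd = (rcs_basis(x + eps, knots) - rcs_basis(x - eps, knots)) / (2 * eps)
        np.testing.assert_allclose(rcs_basis_deriv(x, knots), fd, atol=1e-6)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([np.nan]), [0.0, 1.0])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        hst.lists(
            hst.floats(-2.0, 3.0, allow_nan=False), min_size=3, max_size=6, unique=True
        ),
        hst.floats(0.1, 5.0, allow_nan=False),
    )
    def test_tail_linearity_for_arbitrary_knots(self, knot_vals, offset):
        # restricted basis is linear beyond either boundary knot, whatever the knots
        knots = np.sort(np.asarray(knot_vals))
        assume(np.min(np.diff(knots)) > 0.05)
        for x0 in (knots[-1] + offset, knots[0] - offset):
            h = 0.01
            B = rcs_basis(np.array([x0 - h, x0, x0 + h]), knots)
            np.testing.assert_allclose(B[0] - 2 * B[1] + B[2], 0.0, atol=1e-7)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hst.floats(-1.5, 2.5, allow_nan=False))
    def test_basis_row_sums_continuous_in_x(self, x0):
        # basis columns are individually continuous: nearby x give nearby rows
        knots = np.array([-1.0, 0.2, 1.0, 2.5])
        a = rcs_basis(np.array([x0]), knots)
        b = rcs_basis(np.array([x0 + 1e-7]), knots)
        np.testing.assert_allclose(a, b, atol=1e-5)


class TestKnotPlacement:
    def test_geometric_midpoint_of_extrapolation_segment(self):
        knots, _ = xs.place_knots(5.0, 40.0, np.array([0.2, 1.0, 4.0]))
        # midpoint on the log scale between 5 and 40 years is sqrt(200) ~ 14.142
        assert np.exp(knots[2]) == pytest.approx(np.sqrt(200.0), rel=1e-12)

    def test_two_internal_knots_and_boundaries_at_data_ends(self):
        knots, knots_trt = xs.place_knots(5.0, 40.0, np.array([0.37, 2.0]))
        assert len(knots) == 4  # 2 boundary + 2 internal
        assert np.exp(knots[0]) == pytest.approx(0.37)
        assert np.exp(knots[-1]) == pytest.approx(40.0)
        # treatment spline: trial-segment boundaries with one internal knot at the log-midpoint
        assert len(knots_trt) == 3
        assert np.exp(knots_trt[1]) == pytest.approx(np.sqrt(0.37 * 5.0), rel=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            xs.place_knots(5.0, 40.0, np.array([40.0]))
        with pytest.raises(ValueError):
            xs.place_knots(40.0, 5.0, np.array([1.0]))
        with pytest.raises(ValueError):
            xs.place_knots(5.0, 40.0, np.array([]))


def _fixed_model():
    """Spline model with fixed, well-conditioned knots for closed-form checks."""
    return xs.SplineTwoArmModel(np.log([0.3, 1.0, 14.0, 40.0]), np.log([0.3, 1.2, 5.0]))


G0 = np.array([-1.0, 1.2, 0.05, -0.02])  # a valid control coefficient vector


class TestSplineModel:
    def test_no_internal_knots_is_exactly_weibull(self, trial):
        # log H = a + b log t is Weibull with shape b, scale exp(-a/b)
        k, sigma = 1.3, 7.0
        model = xs.SplineTwoArmModel(np.log([0.3, 40.0]), np.log([0.3, 5.0]))
        params = np.array([-k * np.log(sigma), k, 0.0, 0.0])
        wb = xs.build_two_arm_model("weibull", "PH")
        wb_params = np.array([np.log(k), np.log(sigma), 0.0])
        ll_spline = xs.trial_log_likelihood(trial, model, params)
        ll_weibull = xs.trial_log_likelihood(trial, wb, wb_params)
        assert ll_spline == pytest.approx(ll_weibull, abs=1e-8)
        t = np.array([1.0, 5.0, 20.0])
        np.testing.assert_allclose(
            model.survival(params, t, 0), wb.survival(wb_params, t, 0), rtol=1e-12
        )

    def test_zero_treatment_spline_gives_identical_arms(self):
        model = _fixed_model()
        params = np.concatenate([G0, np.zeros(model.n_gamma_trt)])
        assert model.valid(params)
        t = np.geomspace(0.5, 39.0, 25)
        np.testing.assert_array_equal(
            model.survival(params, t, 0), model.survival(params, t, 1)
        )
        np.testing.assert_allclose(xs.hazard_ratio_curve(model, params, t), 1.0, rtol=1e-12)

    def test_hazard_matches_finite_difference_of_cum_hazard(self):
        model = _fixed_model()
        params = np.concatenate([G0, [0.1, -0.2, 0.05]])
        assert model.valid(params)
        t = np.geomspace(0.5, 30.0, 30)
        eps = 1e-6
        for arm in (0, 1):
            H_hi = model.cum_hazard(params, t * (1 + eps), arm)
            H_lo = model.cum_hazard(params, t * (1 - eps), arm)
            fd = (H_hi - H_lo) / (2 * eps * t)
            np.testing.assert_allclose(model.hazard(params, t, arm), fd, rtol=1e-5)

    def test_constant_treatment_offset_is_proportional_hazards(self):
        # treatment basis contributing only an intercept c leaves HR = e^c at all t
        model = _fixed_model()
        params = np.concatenate([G0, [0.7, 0.0, 0.0]])
        assert model.valid(params)
        t = np.geomspace(0.5, 39.0, 40)
        np.testing.assert_allclose(
            xs.hazard_ratio_curve(model, params, t), np.exp(0.7), rtol=1e-10
        )

    def test_validity_filter_rejects_decreasing_log_cum_hazard(self):
        model = _fixed_model()
        good = np.concatenate([G0, np.zeros(model.n_gamma_trt)])
        assert model.valid(good)
        bad = good.copy()
        bad[1] = -0.5  # negative slope: H decreasing
        assert not model.valid(bad)
        # treatment-arm violation: strong negative treatment slope
        bad_trt = good.copy()
        bad_trt[model.n_gamma0 + 1] = -5.0
        assert not model.valid(bad_trt)

    def test_conditional_survival_identity(self, spline_model):
        params = np.array([-1.0, 1.1, 0.04, -0.01, 0.0, 0.0, 0.0])[: spline_model.n_params]
        t = np.array([2.0, 6.0, 20.0])
        cs = xs.conditional_survival(spline_model, params, 0, t)
        direct = spline_model.survival(params, t, 0) / spline_model.survival(params, t - 1.0, 0)
        np.testing.assert_allclose(cs, direct, rtol=1e-10)

    def test_treatment_spline_allows_single_turning_point_hr(self):
        # a dip-then-recover hazard ratio is representable: fitted-shape smoke check
        model = _fixed_model()
        params = np.concatenate([G0, [-0.05, -0.2, -0.034]])
        assert model.valid(params)
        t = np.linspace(0.3, 5.0, 200)
        hr = xs.hazard_ratio_curve(model, params, t)
        d = np.diff(hr)
        sign_changes = int(np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0))
        assert sign_changes == 1  # decreases, turns once, then recovers
        imin = int(np.argmin(hr))
        assert 0 < imin < len(hr) - 1
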