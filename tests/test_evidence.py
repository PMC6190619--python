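"""External-evidence likelihood contributions."""

import numpy as np
import pytest
from scipy import stats

import extrasurv as xs
from extrasurv.data import DataValidationError


@pytest.fixture
def exp_model():
    return xs.build_two_arm_model("exponential", "PH")


EXP_PARAMS = np.array([np.log(0.11), -0.2])


class TestGPSurvival:
    def test_binomial_term_matches_scipy_oracle(self, exp_model):
        point = xs.GPSurvivalPoint(1660, 158858, 40.0)
        s0 = float(exp_model.survival(EXP_PARAMS, np.array([40.0]), 0)[0])
        beta = 0.002
        ll = xs.gp_survival_loglik(exp_model, EXP_PARAMS, point, beta)
        assert ll == pytest.approx(stats.binom.logpmf(1660, 158858, s0 + beta), rel=1e-10)

    def test_maximizing_probability_is_empirical_proportion(self, exp_model):
        # profile over beta: the binomial is maximized at p = r/n = 1.045%
        point = xs.GPSurvivalPoint(1660, 158858, 40.0)
        params = np.array([np.log(0.15), -0.2])  # S0(40) ~ 0.25%, below the GP level
        s0 = float(exp_model.survival(params, np.array([40.0]), 0)[0])
        p_grid = np.linspace(0.005, 0.02, 3001)
        lls = [xs.gp_survival_loglik(exp_model, params, point, p - s0) for p in p_grid]
        p_best = p_grid[int(np.argmax(lls))]
        assert 100 * p_best == pytest.approx(1.045, abs=2e-3)
        assert round(point.survival_percent, 3) == 1.045

    def test_domain_edges_flagged(self, exp_model):
        point = xs.GPSurvivalPoint(10, 10, 40.0)
        s0 = float(exp_model.survival(EXP_PARAMS, np.array([40.0]), 0)[0])
        assert xs.gp_survival_loglik(exp_model, EXP_PARAMS, point, 1.0 - s0) == -np.inf
        assert xs.gp_survival_loglik(exp_model, EXP_PARAMS, point, -0.01) == -np.inf
        assert xs.gp_survival_loglik(exp_model, EXP_PARAMS, point, 0.0) == -np.inf

    def test_invalid_counts_rejected(self):
        with pytest.raises(DataValidationError):
            xs.GPSurvivalPoint(11, 10, 40.0)


class TestConditionalSurvival:
    def test_exponential_memorylessness(self, exp_model):
        lam = np.exp(EXP_PARAMS[0])
        cs = xs.conditional_survival(exp_model, EXP_PARAMS, 0, np.array([1.0, 5.0, 30.0]))
        np.testing.assert_allclose(cs, np.exp(-lam), rtol=1e-12)

    def test_first_year_conditional_equals_survival(self, exp_model):
        cs1 = xs.conditional_survival(exp_model, EXP_PARAMS, 0, np.array([1.0]))[0]
        assert cs1 == pytest.approx(float(exp_model.survival(EXP_PARAMS, np.array([1.0]), 0)[0]))

    def test_ratio_identity_for_spline_draw(self, spline_model):
        params = np.array([-1.0, 1.1, 0.04, -0.01, 0.0, 0.0, 0.0])[: spline_model.n_params]
        t = np.array([6.0, 15.0, 26.0])
        cs = xs.conditional_survival(spline_model, params, 0, t)
        S = spline_model.survival(params, t, 0)
        S_prev = spline_model.survival(params, t - 1, 0)
        np.testing.assert_allclose(cs, S / S_prev, rtol=1e-10)


class TestRegistrySeries:
    def _series(self, model, params, years, n=200, at_mode=True, rng=None):
        cs = xs.conditional_survival(model, params, 0, np.asarray(years, float))
        if at_mode:
            r = np.round(n * cs).astype(int)
        else:
            r = rng.binomial(n, cs)
        return xs.ConditionalSurvivalSeries(tuple(years), tuple(int(x) for x in r), tuple([n] * len(years)))

    def test_default_year_range_has_21_terms(self):
        series = xs.generate_registry_series(xs.ScenarioConfig(), seed=3)
        assert len(series) == 21
        assert series.years[0] == 6.0 and series.years[-1] == 26.0

    def test_sum_matches_per_year_scipy_oracle(self, exp_model):
        years = list(range(6, 27))
        rng = np.random.default_rng(0)
        series = self._series(exp_model, EXP_PARAMS, years, at_mode=False, rng=rng)
        total = xs.registry_conditional_loglik(exp_model, EXP_PARAMS, series)
        cs = xs.conditional_survival(exp_model, EXP_PARAMS, 0, np.asarray(years, float))
        expected = sum(
            stats.binom.logpmf(r, n, p) for r, n, p in zip(series.r, series.n, cs)
        )
        assert total == pytest.approx(expected, rel=1e-10)

    def test_years_must_increase(self):
        with pytest.raises(DataValidationError):
            xs.ConditionalSurvivalSeries((6.0, 6.0), (1, 1), (2, 2))


class TestGPConditional:
    def test_single_entry_equals_registry_kernel(self, exp_model):
        entry = xs.ConditionalSurvivalSeries((35.0,), (150,), (180,), source="general_population")
        assert xs.gp_conditional_loglik(exp_model, EXP_PARAMS, entry) == pytest.approx(
            xs.registry_conditional_loglik(exp_model, EXP_PARAMS, entry), rel=1e-12
        )

    def test_zero_survivors_closed_form(self, exp_model):
        entry = xs.ConditionalSurvivalSeries((35.0,), (0,), (50,))
        cs = float(xs.conditional_survival(exp_model, EXP_PARAMS, 0, np.array([35.0]))[0])
        assert xs.gp_conditional_loglik(exp_model, EXP_PARAMS, entry) == pytest.approx(
            50 * np.log1p(-cs), rel=1e-10
        )


class TestHRPseudo:
    def test_perfect_hazard_ratio_attains_gaussian_peak(self):
        # HR(t) == 1 under PH with beta=0: 30 terms, each at the N(1, 0.1^2) mode
        model = xs.build_two_arm_model("exponential", "PH")
        params = np.array([np.log(0.2), 0.0])
        pseudo = xs.HRPseudoData()
        assert len(pseudo) == 30
        expected = 30 * np.log(1.0 / (0.1 * np.sqrt(2 * np.pi)))
        assert xs.hr_pseudo_loglik(model, params, pseudo) == pytest.approx(expected, rel=1e-10)

    def test_one_sd_off_costs_half_per_term(self):
        model = xs.build_two_arm_model("exponential", "PH")
        params = np.array([np.log(0.2), np.log(1.1)])  # HR = 1.1 everywhere
        pseudo = xs.HRPseudoData()
        peak = 30 * np.log(1.0 / (0.1 * np.sqrt(2 * np.pi)))
        got = xs.hr_pseudo_loglik(model, params, pseudo)
        per_term = (peak - got) / 30
        assert per_term == pytest.approx(0.5, abs=1e-10)

    def test_arbitrary_curve_matches_scipy_oracle(self):
        model = xs.SplineTwoArmModel(np.log([0.3, 1.0, 14.0, 40.0]), np.log([0.3, 1.2, 5.0]))
        params = np.array([-1.0, 1.2, 0.05, -0.02, -0.05, -0.1, 0.04])
        assert model.valid(params)
        pseudo = xs.HRPseudoData(times=tuple(range(6, 36)), value=1.0, sd=0.07)
        hr = xs.hazard_ratio_curve(model, params, np.asarray(pseudo.times, float))
        expected = stats.norm.logpdf(1.0, loc=hr, scale=0.07).sum()
        assert xs.hr_pseudo_loglik(model, params, pseudo) == pytest.approx(expected, rel=1e-10)

    def test_sd_must_be_positive(self):
        with pytest.raises(DataValidationError):
            xs.HRPseudoData(sd=0.0)


class TestAssembly:
    def test_no_active_sources_gives_zero(self, exp_model):
        assert xs.assemble_evidence_loglik(exp_model, EXP_PARAMS, None) == 0.0
        assert xs.assemble_evidence_loglik(exp_model, EXP_PARAMS, xs.ExternalEvidence()) == 0.0

    def test_all_sources_additive(self, exp_model, evidence):
        beta = 0.004
        total = xs.assemble_evidence_loglik(exp_model, EXP_PARAMS, evidence, beta)
        parts = [
            xs.gp_survival_loglik(exp_model, EXP_PARAMS, evidence.gp_survival, beta),
            xs.registry_conditional_loglik(exp_model, EXP_PARAMS, evidence.registry_cs),
            xs.gp_conditional_loglik(exp_model, EXP_PARAMS, evidence.gp_cs),
            xs.hr_pseudo_loglik(exp_model, EXP_PARAMS, evidence.hr_pseudo),
        ]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_two_source_subset(self, exp_model, evidence):
        sub = xs.ExternalEvidence(registry_cs=evidence.registry_cs, gp_cs=evidence.gp_cs)
        total = xs.assemble_evidence_loglik(exp_model, EXP_PARAMS, sub)
        expected = xs.registry_conditional_loglik(
            exp_model, EXP_PARAMS, evidence.registry_cs
        ) + xs.gp_conditional_loglik(exp_model, EXP_PARAMS, evidence.gp_cs)
        assert total == pytest.approx(expected, rel=1e-12)
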