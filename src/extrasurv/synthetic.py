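"""Synthetic study generator: a two-arm trial plus all four external-evidence datasets.

The generator emulates the statistical structure of a head-and-neck-cancer
extrapolation problem:

* a two-arm RCT (default 213 control / 211 treatment) with a control-arm
  hazard that rises over the first years and then plateaus, administrative
  censoring at 5 years, and a treatment hazard ratio that starts near 1,
  dips, and returns to 1 by year 6 (piecewise-constant segments, so event
  times are drawn by exact inverse transform of the cumulative hazard);
* an age-matched general-population cohort (default n = 158,858) with a
  Gompertz (exponentially age-increasing) hazard calibrated so that
  40-year survival is about 1.045%;
* a registry conditional-survival series for years 6-26 whose level is a
  constant relative factor (default 0.95) below the general population's
  1-year conditional survival — gently declining in absolute terms and, by
  construction, always below the general-population series;
* hazard-ratio pseudo-data (value 1, sd 0.1, years 6-35).

Beyond the trial period the generating control-arm hazard is the
general-population hazard plus the constant excess implied by the relative
factor, so the registry series is drawn from the scenario's own truth.

All randomness flows from a single seed through independent spawned
streams, so each dataset is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ARM_CONTROL, ARM_TREATMENT, TrialData
from .evidence import (
    ConditionalSurvivalSeries,
    ExternalEvidence,
    GPSurvivalPoint,
    HRPseudoData,
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating parameters for one synthetic study."""

    n_control: int = 213
    n_treatment: int = 211
    #: control-arm piecewise-constant hazard: rates on [0,b1), [b1,b2), [b2, trial tail)
    control_breaks: tuple = (1.0, 3.0)
    control_rates: tuple = (0.08, 0.13, 0.14)
    #: hazard-ratio trajectory: levels on segments split at hr_breaks (starts near 1,
    #: dips, back to exactly 1 from the last break on)
    hr_breaks: tuple = (1.0, 3.0, 6.0)
    hr_levels: tuple = (0.9, 0.6, 0.8, 1.0)
    admin_censor: float = 5.0
    trial_end: float = 5.0
    external_end: float = 40.0
    horizon: float = 60.0
    #: general-population cohort: size, 40-year survival target, Gompertz slope /yr
    gp_n: int = 158858
    gp_survival_40: float = 0.01045
    gompertz_b: float = 0.105
    #: registry conditional survival = registry_relative * GP conditional survival
    registry_relative: float = 0.95
    registry_n0: int = 150
    registry_years: tuple = (6, 26)
    hr_pseudo_value: float = 1.0
    hr_pseudo_sd: float = 0.1
    hr_pseudo_years: tuple = (6, 35)

    def __post_init__(self):
        if any(r <= 0 for r in self.control_rates):
            raise ValueError("hazard rates must be > 0")
        if any(h <= 0 for h in self.hr_levels):
            raise ValueError("hazard-ratio levels must be > 0")
        if len(self.control_rates) != len(self.control_breaks) + 1:
            raise ValueError("need one more control rate than break")
        if len(self.hr_levels) != len(self.hr_breaks) + 1:
            raise ValueError("need one more HR level than break")
        if not 0 < self.admin_censor <= self.trial_end:
            raise ValueError("admin censoring must lie in (0, trial_end]")
        if not 0 < self.gp_survival_40 < 1:
            raise ValueError("gp_survival_40 must be in (0,1)")
        if not 0 < self.registry_relative < 1:
            raise ValueError("registry_relative must be in (0,1)")
        if self.hr_pseudo_sd <= 0:
            raise ValueError("hr_pseudo_sd must be > 0")
        if self.hr_pseudo_years[1] > self.horizon:
            raise ValueError("hazard-ratio pseudo-data times must lie within the horizon")


def _piecewise_cum_hazard(t, breaks, rates):
    """Cumulative hazard of a piecewise-constant rate function on [0, inf)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    edges = np.concatenate([[0.0], np.asarray(breaks, float), [np.inf]])
    rates = np.asarray(rates, float)
    H = np.zeros_like(t)
    for i in range(len(rates)):
        lo, hi = edges[i], edges[i + 1]
        H += rates[i] * np.clip(t - lo, 0.0, hi - lo)
    return H


def _piecewise_sample(rng, n, breaks, rates):
    """Exact inverse-transform event times for a piecewise-constant hazard."""
    edges = np.concatenate([[0.0], np.asarray(breaks, float)])
    rates = np.asarray(rates, float)
    H_edges = _piecewise_cum_hazard(edges, breaks, rates)
    E = rng.exponential(size=n)
    idx = np.searchsorted(H_edges, E, side="right") - 1
    return edges[idx] + (E - H_edges[idx]) / rates[idx]


class ScenarioTruth:
    """Closed-form generating curves for one scenario configuration."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        c = config
        # Gompertz level a solved so that H_gp(40) = -log(S_gp(40))
        b = c.gompertz_b
        self.gomp_a = -np.log(c.gp_survival_40) * b / np.expm1(b * c.external_end)
        self.excess = -np.log(c.registry_relative)
        # merged treatment-arm segments: control rate x HR level, piecewise constant
        merged = np.union1d(c.control_breaks, c.hr_breaks)
        self.trt_breaks = tuple(merged)
        edges_mid = np.concatenate([[0.0], merged]) + 1e-9
        ctrl_rate = lambda x: np.asarray(c.control_rates)[
            np.searchsorted(c.control_breaks, x, side="right")
        ]
        hr_level = lambda x: np.asarray(c.hr_levels)[np.searchsorted(c.hr_breaks, x, side="right")]
        self.trt_rates = tuple(float(ctrl_rate(x) * hr_level(x)) for x in edges_mid)

    # -- general population -----------------------------------------------
    def gp_cum_hazard(self, t):
        b = self.config.gompertz_b
        return self.gomp_a / b * np.expm1(b * np.asarray(t, dtype=float))

    def gp_survival(self, t):
        return np.exp(-self.gp_cum_hazard(t))

    def gp_conditional_survival(self, t):
        return np.exp(-(self.gp_cum_hazard(t) - self.gp_cum_hazard(np.asarray(t) - 1.0)))

    # -- control arm --------------------------------------------------------
    def control_cum_hazard(self, t):
        c = self.config
        t = np.atleast_1d(np.asarray(t, dtype=float))
        H_trial = _piecewise_cum_hazard(np.minimum(t, c.trial_end), c.control_breaks, c.control_rates)
        tail = np.clip(t - c.trial_end, 0.0, None)
        H_tail = np.where(
            tail > 0,
            self.gp_cum_hazard(t) - self.gp_cum_hazard(c.trial_end) + self.excess * tail,
            0.0,
        )
        return H_trial + H_tail

    def control_survival(self, t):
        return np.exp(-self.control_cum_hazard(t))

    def control_conditional_survival(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-(self.control_cum_hazard(t) - self.control_cum_hazard(t - 1.0)))

    def hazard_ratio(self, t):
        c = self.config
        return np.asarray(c.hr_levels)[np.searchsorted(c.hr_breaks, np.asarray(t), side="right")]


# -- generators -------------------------------------------------------------


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_trial(config: ScenarioConfig, seed: int) -> TrialData:
    """Two-arm trial IPD with administrative censoring, by exact inverse transform."""
    truth = ScenarioTruth(config)
    rng_c, rng_t = _spawn(seed, 2)
    t0 = _piecewise_sample(rng_c, config.n_control, config.control_breaks, config.control_rates)
    t1 = _piecewise_sample(rng_t, config.n_treatment, truth.trt_breaks, truth.trt_rates)
    times, events, arms = [], [], []
    for t_arm, arm in ((t0, ARM_CONTROL), (t1, ARM_TREATMENT)):
        cens = t_arm >= config.admin_censor
        times.append(np.where(cens, config.admin_censor, t_arm))
        events.append(np.where(cens, 0, 1))
        arms.append(np.full(t_arm.shape, arm))
    return TrialData(
        np.concatenate(times), np.concatenate(events), np.concatenate(arms),
        max_follow_up=config.admin_censor,
    )


def generate_gp_cohort(
    config: ScenarioConfig, seed: int
) -> tuple[GPSurvivalPoint, ConditionalSurvivalSeries]:
    """Matched general-population cohort: the 40-year survivor count and the
    late conditional-survival point (35 | 34), drawn jointly from the same
    generating life table so the counts nest consistently."""
    truth = ScenarioTruth(config)
    (rng,) = _spawn(seed, 1)
    n = config.gp_n
    S = truth.gp_survival(np.array([34.0, 35.0, config.external_end]))
    r34 = rng.binomial(n, S[0])
    r35 = rng.binomial(r34, S[1] / S[0])
    r40 = rng.binomial(r35, S[2] / S[1])
    point = GPSurvivalPoint(int(r40), n, config.external_end)
    cs = ConditionalSurvivalSeries((35.0,), (int(r35),), (int(r34),), source="general_population")
    return point, cs


def generate_registry_series(config: ScenarioConfig, seed: int) -> ConditionalSurvivalSeries:
    """Registry 1-year conditional-survival counts, years 6..26 by default.

    Success probabilities come from the scenario's generating control-arm
    curve (registry_relative x the general-population conditional survival);
    survivors of year t form the denominator for year t+1.
    """
    truth = ScenarioTruth(config)
    (rng,) = _spawn(seed, 1)
    y0, y1 = config.registry_years
    years = list(range(int(y0), int(y1) + 1))
    n_t = config.registry_n0
    rs, ns = [], []
    for t in years:
        cs = float(np.atleast_1d(truth.control_conditional_survival(float(t)))[0])
        r = int(rng.binomial(n_t, cs))
        rs.append(r)
        ns.append(n_t)
        n_t = max(r, 1)
    return ConditionalSurvivalSeries(tuple(float(y) for y in years), tuple(rs), tuple(ns))


def generate_hr_pseudo(config: ScenarioConfig) -> HRPseudoData:
    """Deterministic hazard-ratio pseudo-data (value 1 at years 6..35, sd 0.1)."""
    y0, y1 = config.hr_pseudo_years
    return HRPseudoData(
        tuple(float(t) for t in range(int(y0), int(y1) + 1)),
        config.hr_pseudo_value,
        config.hr_pseudo_sd,
    )


def generate_scenario(
    config: ScenarioConfig | None = None, seed: int = 0
) -> tuple[TrialData, ExternalEvidence, ScenarioTruth]:
    """One full synthetic study: trial IPD, all four evidence sources, and the truth."""
    if config is None:
        config = ScenarioConfig()
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(3)]
    trial = generate_trial(config, seeds[0])
    gp_point, gp_cs = generate_gp_cohort(config, seeds[1])
    registry = generate_registry_series(config, seeds[2])
    evidence = ExternalEvidence(
        gp_survival=gp_point, registry_cs=registry, gp_cs=gp_cs,
        hr_pseudo=generate_hr_pseudo(config),
    )
    return trial, evidence, ScenarioTruth(config)
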