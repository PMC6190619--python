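"""External-evidence likelihood contributions, written in terms of the survival model.

Four sources, each contributing a likelihood term evaluated at the trial
survival model's own parameters, so that one joint posterior is estimated
from all data simultaneously:

1. General-population survival at a late horizon t* (default 40 years):
   r ~ Binomial(n, S_GP(t*)) with S_GP(t*) = S0(t*) + beta, beta > 0, which
   encodes that control-arm survival can be no better than the matched
   general population.
2. Registry (e.g. SEER) 1-year conditional survival at years t = 6..26:
   r_t ~ Binomial(n_t, CS0(t | t-1)) with the model's own conditional
   survival S0(t)/S0(t-1) as the success probability (a hard equality).
3. General-population 1-year conditional survival at one late time point
   (default 35 | 34), same binomial form as 2.
4. Hazard-ratio pseudo-data: HR_obs(t) = value (default 1) observed with a
   normal error (default sd 0.1) around the model hazard ratio h1(t)/h0(t)
   at t = 6..35, expressing a treatment effect that has waned by year 6.

All functions return ``-inf`` as an invalid-parameter flag (never raise)
when a probability leaves its domain, so MCMC simply rejects the draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data import ARM_CONTROL, ARM_TREATMENT, DataValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


def _binom_logpmf(r, n, p) -> float:
    """Binomial log-pmf via gammaln (fast enough for an MCMC inner loop)."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        return -np.inf
    coef = special.gammaln(n + 1) - special.gammaln(r + 1) - special.gammaln(n - r + 1)
    val = coef + special.xlogy(r, p) + special.xlog1py(n - r, -p)
    total = float(np.sum(val))
    return total if np.isfinite(total) else -np.inf


@dataclass(frozen=True)
class GPSurvivalPoint:
    """Survivor count r out of n at horizon t_star in the matched general population."""

    r: int
    n: int
    t_star: float = 40.0

    def __post_init__(self):
        if not 0 <= self.r <= self.n:
            raise DataValidationError(f"need 0 <= r <= n, got r={self.r}, n={self.n}")
        if self.t_star <= 0:
            raise DataValidationError("t_star must be > 0")

    @property
    def survival_percent(self) -> float:
        """Observed survival proportion r/n as a percentage."""
        return 100.0 * self.r / self.n


@dataclass(frozen=True)
class ConditionalSurvivalSeries:
    """Per-year 1-year conditional survival counts (t, r, n), e.g. from a registry."""

    years: tuple
    r: tuple
    n: tuple
    source: str = "registry"

    def __post_init__(self):
        years = np.asarray(self.years, dtype=float)
        r = np.asarray(self.r, dtype=float)
        n = np.asarray(self.n, dtype=float)
        if not (years.size == r.size == n.size):
            raise DataValidationError("years, r, n must have equal length")
        if years.size and np.any(np.diff(years) <= 0):
            raise DataValidationError("years must be strictly increasing")
        if np.any(r < 0) or np.any(r > n):
            raise DataValidationError("need 0 <= r <= n per entry")

    def __len__(self):
        return len(self.years)

    @classmethod
    def from_entries(cls, entries, source="registry"):
        entries = sorted(entries, key=lambda e: e["t"])
        return cls(
            tuple(e["t"] for e in entries),
            tuple(e["r"] for e in entries),
            tuple(e["n"] for e in entries),
            source,
        )


@dataclass(frozen=True)
class HRPseudoData:
    """Pseudo-observations of the hazard ratio: value observed at each time with sd."""

    times: tuple = tuple(range(6, 36))
    value: float = 1.0
    sd: float = 0.1

    def __post_init__(self):
        if self.sd <= 0:
            raise DataValidationError("hazard-ratio pseudo-data sd must be > 0")
        if any(t <= 0 for t in self.times):
            raise DataValidationError("pseudo-data times must be > 0")

    def __len__(self):
        return len(self.times)


@dataclass
class ExternalEvidence:
    """The active subset of the four external-evidence sources."""

    gp_survival: GPSurvivalPoint | None = None
    registry_cs: ConditionalSurvivalSeries | None = None
    gp_cs: ConditionalSurvivalSeries | None = None
    hr_pseudo: HRPseudoData | None = None

    @property
    def needs_beta(self) -> bool:
        return self.gp_survival is not None

    def active_sources(self) -> list[str]:
        out = []
        if self.gp_survival is not None:
            out.append("gp_survival")
        if self.registry_cs is not None:
            out.append("registry_cs")
        if self.gp_cs is not None:
            out.append("gp_cs")
        if self.hr_pseudo is not None:
            out.append("hr_pseudo")
        return out


# -- likelihood contributions ---------------------------------------------


def conditional_survival(model, params, arm, t) -> np.ndarray:
    """1-year conditional survival CS(t | t-1) = S(t)/S(t-1) under the model."""
    t = np.asarray(t, dtype=float)
    with np.errstate(all="ignore"):
        H_t = model.cum_hazard(params, t, arm)
        H_prev = model.cum_hazard(params, np.maximum(t - 1.0, 0.0), arm)
        # S(0)=1 so H(t-1)=0 when t<=1
        H_prev = np.where(t - 1.0 <= 0, 0.0, H_prev)
        return np.exp(-(H_t - H_prev))


def gp_survival_loglik(model, params, point: GPSurvivalPoint, beta: float) -> float:
    """Eq-1-style binomial term: r ~ Binomial(n, S0(t*) + beta), beta > 0."""
    if not (np.isfinite(beta) and beta > 0):
        return -np.inf
    with np.errstate(all="ignore"):
        s0 = float(model.survival(params, np.array([point.t_star]), ARM_CONTROL)[0])
    p = s0 + beta
    if not (0.0 < p < 1.0):
        return -np.inf
    return _binom_logpmf(point.r, point.n, p)


def _cs_series_loglik(model, params, series: ConditionalSurvivalSeries) -> float:
    cs = conditional_survival(model, params, ARM_CONTROL, np.asarray(series.years, float))
    if np.any(~np.isfinite(cs)):
        return -np.inf
    return _binom_logpmf(np.asarray(series.r, float), np.asarray(series.n, float), cs)


def registry_conditional_loglik(model, params, series: ConditionalSurvivalSeries) -> float:
    """Sum of binomial terms with probability equal to the model's control-arm CS."""
    return _cs_series_loglik(model, params, series)


def gp_conditional_loglik(model, params, point: ConditionalSurvivalSeries) -> float:
    """Single conditional-survival binomial term (default at 35 | 34); same kernel."""
    return _cs_series_loglik(model, params, point)


def hr_pseudo_loglik(model, params, pseudo: HRPseudoData) -> float:
    """Normal pseudo-likelihood for the hazard ratio at late times."""
    t = np.asarray(pseudo.times, dtype=float)
    with np.errstate(all="ignore"):
        log_hr = model.log_hazard(params, t, ARM_TREATMENT) - model.log_hazard(
            params, t, ARM_CONTROL
        )
        hr = np.exp(log_hr)
    if np.any(~np.isfinite(hr)):
        return -np.inf
    z = (pseudo.value - hr) / pseudo.sd
    val = float(np.sum(-0.5 * z**2 - np.log(pseudo.sd) - 0.5 * _LOG_2PI))
    return val if np.isfinite(val) else -np.inf


def evidence_logliks(model, params, evidence: ExternalEvidence | None, beta: float | None = None):
    """Per-source log likelihoods as a dict; inactive sources map to None."""
    out = {"gp_survival": None, "registry_cs": None, "gp_cs": None, "hr_pseudo": None}
    if evidence is None:
        return out
    if evidence.gp_survival is not None:
        if beta is None:
            raise ValueError("beta is required when general-population survival is active")
        out["gp_survival"] = gp_survival_loglik(model, params, evidence.gp_survival, beta)
    if evidence.registry_cs is not None:
        out["registry_cs"] = registry_conditional_loglik(model, params, evidence.registry_cs)
    if evidence.gp_cs is not None:
        out["gp_cs"] = gp_conditional_loglik(model, params, evidence.gp_cs)
    if evidence.hr_pseudo is not None:
        out["hr_pseudo"] = hr_pseudo_loglik(model, params, evidence.hr_pseudo)
    return out


def assemble_evidence_loglik(
    model, params, evidence: ExternalEvidence | None, beta: float | None = None
) -> float:
    """Sum of the active external-evidence contributions (0 when none active)."""
    parts = [v for v in evidence_logliks(model, params, evidence, beta).values() if v is not None]
    return float(sum(parts)) if parts else 0.0
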