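"""The menu of parametric survival families and arm-link structures.

Families: Exponential, Weibull, two-parameter Gamma, Log-logistic, Log-normal
and Generalized Gamma. Every positive-constrained parameter is stored on the
log scale so the sampling space is unconstrained reals; the Generalized Gamma
uses the stable log-time location/scale/shape parameterization (mu, sigma, Q),
which reduces to Weibull at Q=1 and to Log-normal at Q=0.

Arm links:

* ``PH``   — proportional hazards, h1(t) = h0(t) * exp(beta)
* ``AFT``  — accelerated failure time, S1(t) = S0(t * exp(-beta))
* ``FSEA`` — fitted separately to each arm (independent parameter vectors)
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .data import ARM_CONTROL, TrialData

LINKS = ("PH", "AFT", "FSEA")


class ConfigurationError(ValueError):
    """Raised for an unsupported model configuration."""


class BaseFamily:
    name: str = ""
    n_params: int = 0
    param_names: tuple[str, ...] = ()

    def log_hazard(self, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cum_hazard(self, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hazard(self, theta, t):
        return np.exp(self.log_hazard(theta, np.asarray(t, dtype=float)))

    def survival(self, theta, t):
        return np.exp(-self.cum_hazard(theta, np.asarray(t, dtype=float)))

    def initial_theta(self, rate: float) -> np.ndarray:
        """Crude starting values matched to an exponential with the given event rate."""
        raise NotImplementedError


class Exponential(BaseFamily):
    name = "exponential"
    n_params = 1
    param_names = ("log_rate",)

    def log_hazard(self, theta, t):
        return np.full_like(np.asarray(t, dtype=float), theta[0])

    def cum_hazard(self, theta, t):
        return np.exp(theta[0]) * np.asarray(t, dtype=float)

    def initial_theta(self, rate):
        return np.array([np.log(rate)])


class Weibull(BaseFamily):
    name = "weibull"
    n_params = 2
    param_names = ("log_shape", "log_scale")

    def log_hazard(self, theta, t):
        k, logsig = np.exp(theta[0]), theta[1]
        logt = np.log(np.asarray(t, dtype=float))
        return theta[0] - logsig + (k - 1.0) * (logt - logsig)

    def cum_hazard(self, theta, t):
        k = np.exp(theta[0])
        return np.exp(k * (np.log(np.asarray(t, dtype=float)) - theta[1]))

    def initial_theta(self, rate):
        return np.array([0.0, -np.log(rate)])


class Gamma2(BaseFamily):
    """Two-parameter Gamma with shape a and rate b (scale 1/b)."""

    name = "gamma2"
    n_params = 2
    param_names = ("log_shape", "log_rate")

    def _sf_logpdf(self, theta, t):
        a, b = np.exp(theta[0]), np.exp(theta[1])
        x = b * np.asarray(t, dtype=float)
        logpdf = theta[1] + special.xlogy(a - 1.0, x) - x - special.gammaln(a)
        sf = special.gammaincc(a, x)
        return sf, logpdf

    def log_hazard(self, theta, t):
        sf, logpdf = self._sf_logpdf(theta, t)
        with np.errstate(divide="ignore"):
            return logpdf - np.log(sf)

    def cum_hazard(self, theta, t):
        sf, _ = self._sf_logpdf(theta, t)
        with np.errstate(divide="ignore"):
            return -np.log(sf)

    def initial_theta(self, rate):
        return np.array([0.0, np.log(rate)])


class LogLogistic(BaseFamily):
    name = "loglogistic"
    n_params = 2
    param_names = ("log_shape", "log_scale")

    def log_hazard(self, theta, t):
        k, logsig = np.exp(theta[0]), theta[1]
        logt = np.log(np.asarray(t, dtype=float))
        z = k * (logt - logsig)
        return theta[0] - logsig + (k - 1.0) * (logt - logsig) - np.logaddexp(0.0, z)

    def cum_hazard(self, theta, t):
        k = np.exp(theta[0])
        z = k * (np.log(np.asarray(t, dtype=float)) - theta[1])
        return np.logaddexp(0.0, z)

    def initial_theta(self, rate):
        return np.array([0.0, -np.log(rate)])


class LogNormal(BaseFamily):
    name = "lognormal"
    n_params = 2
    param_names = ("mu", "log_sigma")

    def _w(self, theta, t):
        return (np.log(np.asarray(t, dtype=float)) - theta[0]) / np.exp(theta[1])

    def cum_hazard(self, theta, t):
        with np.errstate(divide="ignore"):
            return -stats.norm.logsf(self._w(theta, t))

    def log_hazard(self, theta, t):
        t = np.asarray(t, dtype=float)
        w = self._w(theta, t)
        logpdf = stats.norm.logpdf(w) - theta[1] - np.log(t)
        return logpdf - stats.norm.logsf(w)

    def initial_theta(self, rate):
        return np.array([-np.log(rate), 0.0])


class GenGamma(BaseFamily):
    """Generalized Gamma in the stable (mu, sigma, Q) parameterization.

    S(t) for Q>0 is the upper tail of a Gamma(Q^-2) in u = Q^-2 exp(Q w),
    w = (log t - mu)/sigma; Q<0 flips the tail; Q=0 is the Log-normal limit.
    """

    name = "gengamma"
    n_params = 3
    param_names = ("mu", "log_sigma", "Q")
    _Q_EPS = 1e-8

    def _parts(self, theta, t):
        mu, sigma, Q = theta[0], np.exp(theta[1]), theta[2]
        w = (np.log(np.asarray(t, dtype=float)) - mu) / sigma
        return sigma, Q, w

    def cum_hazard(self, theta, t):
        sigma, Q, w = self._parts(theta, t)
        if abs(Q) < self._Q_EPS:
            with np.errstate(divide="ignore"):
                return -stats.norm.logsf(w)
        gam = Q ** -2
        # u = gam * exp(Q w) computed in log space: for extreme Q/sigma the
        # direct product underflows to 0 while the gamma CDF P(gam, u) ~
        # exp(gam log u - lgamma(gam+1)) is still appreciable; losing that
        # mass fabricates density with no cumulative probability and lets a
        # sampler tunnel into spuriously perfect fits
        log_u = np.log(gam) + Q * w
        tiny = log_u < -700.0
        u = np.exp(np.where(tiny, -700.0, log_u))
        log_cdf_series = gam * log_u - special.gammaln(gam + 1.0)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if Q > 0:
                H = -np.log(special.gammaincc(gam, u))
                H_tiny = -np.log1p(-np.exp(np.minimum(log_cdf_series, 0.0)))
                return np.where(tiny, H_tiny, H)
            # Q < 0: survival is the lower gamma tail
            log_sf = np.where(
                tiny, log_cdf_series, np.log(special.gammainc(gam, u))
            )
            return -log_sf

    def log_hazard(self, theta, t):
        t = np.asarray(t, dtype=float)
        sigma, Q, w = self._parts(theta, t)
        if abs(Q) < self._Q_EPS:
            logpdf = stats.norm.logpdf(w) - theta[1] - np.log(t)
            return logpdf - stats.norm.logsf(w)
        gam = Q ** -2
        logpdf = (
            np.log(abs(Q))
            - np.log(sigma * t)
            + gam * np.log(gam)
            + gam * (Q * w - np.exp(Q * w))
            - special.gammaln(gam)
        )
        return logpdf + self.cum_hazard(theta, t)  # log h = log f - log S = log f + H

    def initial_theta(self, rate):
        return np.array([-np.log(rate), 0.0, 1.0])


FAMILIES: dict[str, BaseFamily] = {
    f.name: f for f in (Exponential(), Weibull(), Gamma2(), LogLogistic(), LogNormal(), GenGamma())
}


class ParametricTwoArmModel:
    """A two-arm survival model: one family plus an arm link.

    The parameter vector layout is ``[theta_control..., beta]`` for PH/AFT and
    ``[theta_control..., theta_treatment...]`` for FSEA. All methods are
    vectorized over ``t``.
    """

    def __init__(self, family: str | BaseFamily, link: str):
        if isinstance(family, str):
            if family not in FAMILIES:
                raise ConfigurationError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
            family = FAMILIES[family]
        if link not in LINKS:
            raise ConfigurationError(f"unknown link {link!r}; choose from {LINKS}")
        self.family = family
        self.link = link
        k = family.n_params
        if link == "FSEA":
            self.n_params = 2 * k
            self.param_names = tuple(f"{p}_ctrl" for p in family.param_names) + tuple(
                f"{p}_trt" for p in family.param_names
            )
        else:
            self.n_params = k + 1
            self.param_names = tuple(family.param_names) + ("beta",)

    @property
    def label(self) -> str:
        return f"{self.family.name} {self.link}"

    def _theta(self, params: np.ndarray, arm: int) -> np.ndarray:
        k = self.family.n_params
        if self.link == "FSEA":
            return params[k:] if arm else params[:k]
        return params[:k]

    def cum_hazard(self, params, t, arm):
        t = np.asarray(t, dtype=float)
        theta = self._theta(params, arm)
        if arm == ARM_CONTROL or self.link == "FSEA":
            return self.family.cum_hazard(theta, t)
        beta = params[-1]
        if self.link == "PH":
            return self.family.cum_hazard(theta, t) * np.exp(beta)
        return self.family.cum_hazard(theta, t * np.exp(-beta))  # AFT

    def log_hazard(self, params, t, arm):
        t = np.asarray(t, dtype=float)
        theta = self._theta(params, arm)
        if arm == ARM_CONTROL or self.link == "FSEA":
            return self.family.log_hazard(theta, t)
        beta = params[-1]
        if self.link == "PH":
            return self.family.log_hazard(theta, t) + beta
        return self.family.log_hazard(theta, t * np.exp(-beta)) - beta  # AFT

    def hazard(self, params, t, arm):
        return np.exp(self.log_hazard(params, t, arm))

    def survival(self, params, t, arm):
        return np.exp(-self.cum_hazard(params, t, arm))

    def valid(self, params: np.ndarray) -> bool:
        """Parametric families are valid on the whole unconstrained space."""
        return bool(np.all(np.isfinite(params)))

    def initial_params(self, data: TrialData) -> np.ndarray:
        """Crude starting point: exponential-equivalent rates per arm, null effect."""
        def crude_rate(arm):
            sub = data.subset(arm)
            if len(sub) == 0 or sub.n_events == 0:
                return 0.1
            return sub.n_events / sub.time.sum()

        if self.link == "FSEA":
            return np.concatenate(
                [self.family.initial_theta(crude_rate(0)), self.family.initial_theta(crude_rate(1))]
            )
        return np.concatenate([self.family.initial_theta(crude_rate(0)), [0.0]])


def build_two_arm_model(family: str, link: str) -> ParametricTwoArmModel:
    """Construct one of the 12-model menu entries (any family x {PH, AFT, FSEA})."""
    return ParametricTwoArmModel(family, link)
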