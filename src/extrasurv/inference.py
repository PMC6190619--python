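"""Joint Bayesian posterior sampling and per-source deviance/DIC accounting.

The posterior combines the trial censored-data likelihood, the active
external-evidence likelihoods and independent Normal(0, variance 1000)
priors on every unconstrained parameter (parameters constrained positive
are sampled on the log scale, so the prior applies to the log parameter).

Sampling uses an affine-invariant ensemble sampler (emcee). Walkers double
as chains for split-Rhat and effective-sample-size diagnostics. Deviance
statistics (Dbar, pD, DIC) are tracked separately for the trial data and
for each type of external evidence, which is what lets a model's fit to
the trial be compared with its fit to each external source.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np

from .data import TrialData, trial_log_likelihood
from .evidence import ExternalEvidence, evidence_logliks

PRIOR_SD = math.sqrt(1000.0)

#: deviance bookkeeping sources; "gp" pools the absolute and conditional
#: general-population terms, as in the per-source fit-statistics tables
SOURCES = ("trial", "registry", "gp", "hr")


class InitializationError(RuntimeError):
    pass


def _prior_logpdf(params: np.ndarray, prior_sd: float = PRIOR_SD) -> float:
    return float(np.sum(-0.5 * (params / prior_sd) ** 2 - np.log(prior_sd) - 0.5 * np.log(2 * np.pi)))


def make_log_posterior(model, data: TrialData, evidence: ExternalEvidence | None = None,
                       prior_sd: float = PRIOR_SD):
    """Build the joint log-posterior callable.

    When general-population survival evidence is active, one extra parameter
    ``b`` is appended to the model's vector with ``beta = exp(b)`` (so the
    survival gap beta is positive by construction) and the same normal prior
    on ``b``. The callable returns ``(log_post, ll_trial, ll_registry,
    ll_gp, ll_hr)``; inactive sources report 0.0.
    """
    needs_beta = evidence is not None and evidence.needs_beta
    ndim = model.n_params + (1 if needs_beta else 0)

    def log_post(params: np.ndarray):
        params = np.asarray(params, dtype=float)
        theta = params[: model.n_params]
        beta = float(np.exp(params[-1])) if needs_beta else None
        if not model.valid(theta):
            return -np.inf, 0.0, 0.0, 0.0, 0.0
        ll_trial = trial_log_likelihood(data, model, theta)
        if not np.isfinite(ll_trial):
            return -np.inf, 0.0, 0.0, 0.0, 0.0
        parts = evidence_logliks(model, theta, evidence, beta)
        ll_registry = parts["registry_cs"] if parts["registry_cs"] is not None else 0.0
        ll_gp = sum(parts[k] for k in ("gp_survival", "gp_cs") if parts[k] is not None)
        ll_hr = parts["hr_pseudo"] if parts["hr_pseudo"] is not None else 0.0
        total = ll_trial + ll_registry + ll_gp + ll_hr + _prior_logpdf(params, prior_sd)
        if not np.isfinite(total):
            return -np.inf, 0.0, 0.0, 0.0, 0.0
        return total, ll_trial, float(ll_registry), float(ll_gp), float(ll_hr)

    log_post.ndim = ndim
    log_post.needs_beta = needs_beta
    return log_post


def log_posterior(params, model, data, evidence=None, prior_sd: float = PRIOR_SD) -> float:
    """Joint log-posterior density at one parameter vector (-inf for invalid draws)."""
    return make_log_posterior(model, data, evidence, prior_sd)(params)[0]


@dataclass
class PosteriorDraws:
    """Retained posterior draws plus per-source log-likelihood traces.

    ``chains`` has shape (n_chains, n_draws, n_params); when general-population
    survival evidence was active the last column is ``b`` with beta = exp(b).
    """

    chains: np.ndarray
    log_prob: np.ndarray
    source_loglik: dict
    param_names: tuple
    seed: int
    has_beta: bool
    rhat: np.ndarray = field(default=None, repr=False)
    ess: np.ndarray = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    @property
    def model_flat(self) -> np.ndarray:
        """Flattened draws restricted to the survival-model parameters."""
        return self.flat[:, : self.flat.shape[1] - (1 if self.has_beta else 0)]

    @property
    def beta(self) -> np.ndarray | None:
        return np.exp(self.flat[:, -1]) if self.has_beta else None

    def flat_source(self, source: str) -> np.ndarray:
        return self.source_loglik[source].reshape(-1)

    def thin(self, step: int) -> "PosteriorDraws":
        return PosteriorDraws(
            self.chains[:, ::step], self.log_prob[:, ::step],
            {k: v[:, ::step] for k, v in self.source_loglik.items()},
            self.param_names, self.seed, self.has_beta, self.rhat, self.ess,
        )

    def max_rhat(self) -> float:
        return float(np.max(self.rhat)) if self.rhat is not None else float("nan")


def _diagnostics(chains: np.ndarray):
    """Split-Rhat and bulk ESS per parameter, via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chains)
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    return np.atleast_1d(rhat), np.atleast_1d(ess)


def sample_posterior(
    model,
    data: TrialData,
    evidence: ExternalEvidence | None = None,
    *,
    seed: int,
    n_walkers: int | None = None,
    n_steps: int = 2000,
    burn_frac: float = 0.5,
    init: np.ndarray | None = None,
    init_scale: float = 0.1,
    prior_sd: float = PRIOR_SD,
    progress: bool = False,
) -> PosteriorDraws:
    """Sample the joint posterior; reproducible given ``seed``.

    Initial walker positions are a Gaussian ball around crude data-based
    estimates (``model.initial_params``); walkers landing on an invalid point
    are re-jittered with a shrinking scale. Warns when split-Rhat > 1.05.
    """
    log_post = make_log_posterior(model, data, evidence, prior_sd)
    ndim = log_post.ndim
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 16)
    if n_walkers % 2:
        n_walkers += 1
    rng = np.random.default_rng(seed)

    if init is None:
        init = model.initial_params(data)
        if log_post.needs_beta:
            init = np.concatenate([init, [np.log(0.01)]])
    init = np.asarray(init, dtype=float)
    if init.size != ndim:
        raise InitializationError(f"init has length {init.size}, model needs {ndim}")

    p0 = np.empty((n_walkers, ndim))
    for w in range(n_walkers):
        scale = init_scale
        for attempt in range(200):
            cand = init + scale * rng.standard_normal(ndim)
            if np.isfinite(log_post(cand)[0]):
                p0[w] = cand
                break
            scale *= 0.8
        else:
            if not np.isfinite(log_post(init)[0]):
                raise InitializationError(
                    "could not find valid initial values; supply `init` explicitly "
                    "(e.g. from a crude Kaplan-Meier-based estimate)"
                )
            p0[w] = init

    blobs_dtype = [(s, float) for s in SOURCES]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_post, blobs_dtype=blobs_dtype)
    sampler.random_state = np.random.RandomState(rng.integers(2**31)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=progress)

    burn = int(burn_frac * n_steps)
    chain = np.swapaxes(sampler.get_chain(discard=burn), 0, 1)  # (walker, step, dim)
    logp = np.swapaxes(sampler.get_log_prob(discard=burn), 0, 1)
    blobs = sampler.get_blobs(discard=burn)
    source_loglik = {s: np.swapaxes(blobs[s], 0, 1) for s in SOURCES}

    rhat, ess = _diagnostics(chain)
    if np.any(rhat > 1.05):
        warnings.warn(
            f"split-Rhat up to {np.max(rhat):.3f} > 1.05: chains may not have converged; "
            "consider more steps or dispersed restarts",
            RuntimeWarning,
            stacklevel=2,
        )

    names = tuple(model.param_names) + (("log_beta",) if log_post.needs_beta else ())
    return PosteriorDraws(chain, logp, source_loglik, names, seed, log_post.needs_beta, rhat, ess)


@dataclass
class FitStatistics:
    """Deviance accounting for one data source: DIC = Dbar + pD, pD = Dbar - D(theta_bar)."""

    source: str
    d_bar: float
    d_hat: float

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_hat

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d

    def as_dict(self) -> dict:
        return {"source": self.source, "d_bar": self.d_bar, "d_hat": self.d_hat,
                "p_d": self.p_d, "dic": self.dic}


def compute_fit_statistics(
    draws: PosteriorDraws, model, data: TrialData, evidence: ExternalEvidence | None = None
) -> dict:
    """Per-source and total deviance statistics from retained draws.

    Dbar is the posterior mean of -2 log L per source (from the traces stored
    during sampling); the plug-in deviance D(theta_bar) is evaluated at the
    posterior mean parameter vector, falling back to the posterior median
    (flagged via a warning) if the mean is an invalid parameter point.
    Sources not in the fit are reported as None, and the total row sums the
    active sources.
    """
    if draws.flat.shape[0] == 0:
        raise ValueError("no retained draws")
    log_post = make_log_posterior(model, data, evidence)
    center = draws.flat.mean(axis=0)
    lp = log_post(center)
    if not np.isfinite(lp[0]):
        warnings.warn(
            "posterior-mean parameter vector is invalid; using posterior median for the "
            "plug-in deviance",
            RuntimeWarning,
            stacklevel=2,
        )
        center = np.median(draws.flat, axis=0)
        lp = log_post(center)
        if not np.isfinite(lp[0]):
            raise ValueError("posterior mean and median are both invalid parameter points")
    plug_in = dict(zip(SOURCES, lp[1:]))

    active = {"trial"}
    if evidence is not None:
        if evidence.registry_cs is not None:
            active.add("registry")
        if evidence.gp_survival is not None or evidence.gp_cs is not None:
            active.add("gp")
        if evidence.hr_pseudo is not None:
            active.add("hr")

    out: dict[str, FitStatistics | None] = {}
    for s in SOURCES:
        if s not in active:
            out[s] = None
            continue
        d_bar = float(np.mean(-2.0 * draws.flat_source(s)))
        stat = FitStatistics(s, d_bar, -2.0 * float(plug_in[s]))
        if stat.p_d < 0:
            warnings.warn(
                f"negative pD ({stat.p_d:.1f}) for source {s!r}: the posterior is far "
                "from normal (skewed or multimodal) and the plug-in deviance exceeds "
                "the posterior mean deviance; reported as-is",
                RuntimeWarning,
                stacklevel=2,
            )
        out[s] = stat
    present = [v for v in out.values() if v is not None]
    out["total"] = FitStatistics(
        "total", sum(v.d_bar for v in present), sum(v.d_hat for v in present)
    )
    return out
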