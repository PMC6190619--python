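# Methods

## The problem

A randomized cancer trial observes survival for a few years; a
cost-effectiveness model needs expected survival over a lifetime. Fitting a
parametric distribution to the trial and integrating its tail answers the
question, but the answer depends heavily on which distribution is chosen —
models that fit the observed window equally well can imply gains in life
expectancy that differ several-fold, because the gain lives in the
unobserved tail. `extrasurv` addresses this by estimating one survival
model jointly from the trial data *and* external evidence about the tail,
within a single Bayesian posterior (multi-parameter evidence synthesis):
every data source contributes a likelihood term written in terms of the
same survival-model parameters.

## Survival models

**Parametric menu.** Exponential, Weibull, two-parameter Gamma,
Log-logistic, Log-normal, and Generalized Gamma, each combinable with three
arm links: proportional hazards (`PH`, h1 = h0·e^β), accelerated failure
time (`AFT`, S1(t) = S0(t·e^(−β))), or independent parameter vectors per
arm (`FSEA`). Positive parameters are sampled on the log scale. The
Generalized Gamma uses the stable log-time location/scale/shape
parameterization (μ, σ, Q), which contains Weibull (Q = 1), Gamma (Q = σ)
and Log-normal (Q = 0) and avoids the classical parameterization's
numerical collapse. The two-parameter Gamma's `AFT` link acts as a time
scale factor, the natural reading for a family without a native
regression form.

**Flexible model.** The control arm's log cumulative hazard is a restricted
(natural) cubic spline in x = log t: log H0(t) = γ0·B(x). A second spline
carries the treatment effect additively on the same scale:
log H1(t) = γ0·B(x) + γ_trt·B_trt(x), so the log hazard-ratio trajectory is
itself a smooth curve rather than a constant. The basis is the
knot-weighted truncated-power form (one coefficient per knot, intercept and
slope included; no orthogonalization), continuously twice-differentiable
inside the boundary knots and exactly linear outside them — the linear
tails are what make 40+-year extrapolation well defined (constant log-H
slope in log-time).

**Knot rule.** Boundary knots at the extreme ends of the data: the smallest
observed event time and the external-evidence horizon (default 40 y).
Internal knots at the midpoint of each data segment on the log-time scale
(geometric midpoints): one inside the trial period, one between the trial
end (5 y) and the evidence horizon — e.g. √(5×40) ≈ 14.1 y. The treatment
spline spans the trial segment with a single internal knot at its
log-midpoint, which permits exactly one turning point in the hazard ratio
(fall then rise), matching the pharmacological expectation for a treatment
that enhances radiotherapy and stops acting within a few years. Whether
the treatment spline should instead share the control spline's full
40-year range is not determined by theory; the trial-range choice is made
here because the hazard-ratio pseudo-data pin the ratio to 1 after year 6
anyway, leaving nothing for a longer treatment spline to estimate.

**Validity.** A spline draw is a valid survival model only if the implied
hazard is positive, i.e. d(log H)/d(log t) > 0. Draws are screened on a
200-point log-spaced grid spanning the boundary knots, for both arms;
failing draws get posterior density −∞ (the likelihood formula is never
altered). Evaluation and screening happen on the same grid, so accepted
draws can in principle dip negative between grid points; at 200 points per
~7 log-units this has never been observed to matter.

## External evidence likelihoods

Four sources, any subset active ("added incrementally"):

1. **General-population survival** at a late horizon t* (default 40 y):
   r ~ Binomial(n, S_GP(t*)) with S_GP(t*) = S0(t*) + β, β > 0. The gap β is
   sampled as β = e^b with the standard prior on b, making the dominance
   S0(t*) < S_GP(t*) strict by construction; the sum is additionally
   required to lie in (0, 1), else the draw is invalid.
2. **Registry conditional survival**: for each year t (default 6…26),
   r_t ~ Binomial(n_t, CS0(t|t−1)) with CS0(t|t−1) = S0(t)/S0(t−1) taken
   directly from the model — a hard equality, no extra noise term.
3. **General-population conditional survival** at one late point (default
   35|34), same binomial kernel as 2. Its role is to reconcile sources 1
   and 2: a registry series below the general population at every year
   would otherwise eventually cross the general-population curve itself.
4. **Hazard-ratio pseudo-data**: HR_obs(t) = 1 observed at t = 6…35 with a
   Normal(h1(t)/h0(t), 0.1²) likelihood, encoding "the treatment effect has
   waned by year 6, with some uncertainty". Shrinking the sd toward 0 pins
   the posterior hazard ratio to 1 over that range.

All likelihood functions return −∞ for out-of-domain probabilities rather
than raising, so the sampler simply rejects.

## Priors, sampling, diagnostics

Every unconstrained parameter (or log parameter) has an independent
Normal(0, variance 1000) prior. Posterior sampling uses an affine-invariant
ensemble sampler (emcee); nothing in the deviance accounting depends on the
sampler, only on a valid MCMC targeting the joint posterior. Defaults:
walkers = max(2·dim + 2, 16), 2000 steps, first 50% discarded as burn-in;
headline spline fits in the examples use 24 walkers × 2500 steps. Initial
positions are a Gaussian ball (scale 0.1, shrinking on rejection) around
crude data-based estimates — exponential-equivalent rates for the
parametric families, a least-squares fit of the control spline to the
Nelson–Aalen log cumulative hazard with a zero treatment spline for the
flexible model. Walkers double as chains for split-R̂ and bulk ESS (via
arviz); a warning is issued when any R̂ > 1.05. Identifiability of spline
coefficients governing the unobserved gap between trial end and the late
evidence is genuinely weak when few sources are active — R̂ surfaces this
(run longer chains or several seeds and compare); it largely disappears
once the conditional-survival series is included.

## Deviance accounting

For each source s, D_s(θ) = −2 log L_s(θ). The per-source posterior mean
deviance D̄_s is averaged over retained draws (tracked during sampling, not
recomputed); the plug-in D_s(θ̄) is evaluated at the posterior mean
parameter vector, falling back to the posterior median (with a warning)
when the mean is an invalid point. Then pD = D̄ − D(θ̄) and DIC = D̄ + pD,
per source and in total (the total rows are exact sums of the active
sources). Because every model's deviance is computed from the same
per-subject likelihood definition, no cross-model rescaling constant is
needed for comparability; that is an intentional simplification relative
to workflows where different tools report deviances on different scales.
pD can be negative when a posterior is far from normal (e.g. the
Generalized Gamma's shape parameter on heavily censored data); it is
reported as-is with a warning. The conventional reading — differences
under ~5 DIC points do not distinguish models — is annotated in the menu
log, never applied automatically.

## Outputs

Mean survival per arm is ∫0^T S(t) dt by composite trapezoid on a log-dense
grid (2049 points, dense near 0), default horizon T = 60 years — survival
in this population is numerically ~0 well before, given a median age at
entry in the late 50s — reported in months (×12, no day-count subtleties).
Doubling the grid moves estimates by < 0.1 month. The gain is the per-draw
treatment–control difference, summarized by posterior mean (the headline),
median, and the central 95% interval; draws whose survival curve is
non-monotone on the grid are excluded and counted. The coefficient of
variation of an interval-summarized estimate is ((hi−lo)/(2·1.96))/|point|.
Curve summaries (S, CS(t|t−1), HR) are per-time posterior quantiles across
draws.

## The synthetic scenario

The generator emulates the *structure* of a head-and-neck-cancer
extrapolation problem, not any particular trial's data:

- **Trial**: 213/211 subjects, piecewise-constant control hazard
  (0.08, 0.13, 0.14)/yr with breaks at 1 and 3 years — hazard rising then
  plateauing, so 1-year conditional survival declines to year 4 and then
  flattens — with administrative censoring at 5 years. The treatment
  hazard ratio is piecewise (0.9, 0.6, 0.8, 1.0) with breaks at 1, 3 and 6
  years: near-null at first, a dip, and return to exactly 1 by year 6.
  Event times come from exact inverse transform of the piecewise
  cumulative hazard.
- **General population**: a Gompertz hazard (slope 0.105/yr, a typical
  adult mortality doubling time) with level calibrated so 40-year survival
  is 1.045%; cohort size 158,858. The 40-year survivor count and the
  (35|34) conditional point are drawn jointly from one life table so the
  counts nest.
- **Registry**: conditional survival equal to 0.95 × the general
  population's — constant on the relative scale, hence gently declining in
  absolute terms and below the general population at every year by
  construction. Year-6 denominator 150, survivors carried forward
  (period-analysis registry cohorts are small and thin out).
- **Post-trial control truth**: general-population hazard plus the constant
  excess −log(0.95), so the registry series is drawn from the scenario's
  own control-arm curve.

All randomness flows from one seed through independently spawned streams
per dataset.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: covariate-driven heterogeneity and the
matching of external cohorts on age/sex/site; calendar-time improvement in
cancer survival; delayed entry between diagnosis and randomization;
non-administrative dropout; and reconstruction error in digitized
Kaplan-Meier data (life tables are accepted as given, deaths placed at
interval midpoints — an explicit, overridable dialect). Note also that the
generating truth (piecewise hazard joined to a Gompertz-plus-excess tail)
is deliberately *not* a member of the spline family: joint fits therefore
show modest per-source deviance penalties relative to single-source
optima. That is the intended behaviour — the per-source accounting exists
precisely to quantify how much each evidence source bends the model — but
it means absolute deviance levels in the examples are scenario properties,
not method benchmarks.

## Numerical choices

- Generalized Gamma tail probabilities are computed in log space: u =
  Q⁻²·exp(Qw) can underflow to zero while the gamma CDF P(Q⁻², u) ≈
  exp(Q⁻²·log u − lnΓ(Q⁻² + 1)) is still appreciable. Without the series
  branch a sampler can tunnel into extreme-(Q, σ) corners where probability
  mass hides below double precision and the likelihood looks spuriously
  perfect.
- Binomial and normal log-densities on the MCMC hot path use gammaln-based
  expressions (scipy.stats objects are used as independent oracles in the
  tests).
- Life-table expansion places deaths at interval midpoints (configurable to
  interval ends); survivors of the last interval are censored at its end so
  counts are preserved exactly.
- Zero follow-up times are rejected at ingest: the log-time scale requires
  t > 0.

## Problem sizes in the test and acceptance runs

Chains are deliberately short where a test checks an identity (deviance
additivity, reparameterization equivalence) and longer where it checks a
posterior property. The coverage calibration uses 20 replicates of a
single-segment (exponential-PH) configuration of the generator — the one
configuration where the generating parameters are exactly a member of the
fitted family, so "the credible interval covers the truth" is well defined
— at 12 walkers × 600 steps; the spline end-to-end recovery check runs one
seed at 24 walkers × 1500 steps with registry pseudo-counts computed from
the generating curve. The acceptance script's joint spline fit uses 24
walkers × 2500 steps on the default scenario.

## Known limitations

- The spline's identifiability between trial end and the first late
  evidence point is data-limited by design; multi-seed R̂ comparison is the
  supported way to surface it.
- pD from the plug-in definition can be negative for non-normal posteriors.
- The hazard-positivity screen is grid-based, not exact.
- FSEA Log-logistic and Log-normal fits can place substantial posterior
  mass on near-defective tails when fitted to trial data alone, producing
  enormous life-expectancy intervals; this is a faithful property of those
  models (and an argument for external evidence), not a sampler artifact.
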