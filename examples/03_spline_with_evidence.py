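"""Joint spline fit: trial data plus all four external-evidence sources.

The control arm's log cumulative hazard is a restricted cubic spline in log
time (boundary knots at the data extremes, internal knots at the
log-midpoints of the trial and extrapolation segments); a second spline
carries the time-varying treatment effect. All likelihoods — trial,
general-population survival, registry conditional survival, and
hazard-ratio pseudo-data — are written in terms of the same parameters, so
one posterior reflects every source, and the deviance is accounted per
source.
"""

import warnings

import numpy as np

import extrasurv as xs

warnings.filterwarnings("ignore")

trial, evidence, _ = xs.generate_scenario(seed=1)
knots, knots_trt = xs.place_knots(5.0, 40.0, trial.time[trial.event == 1])
model = xs.SplineTwoArmModel(knots, knots_trt)
print("control-spline knots (years):", np.round(np.exp(knots), 2))
print("treatment-spline knots (years):", np.round(np.exp(knots_trt), 2))

draws = xs.sample_posterior(model, trial, evidence, seed=7, n_walkers=24, n_steps=2500)
print(f"\nmax split-Rhat: {draws.max_rhat():.3f} "
      f"(walkers treated as chains; values near 1 indicate convergence)")

stats = xs.compute_fit_statistics(draws, model, trial, evidence)
print("\nper-source fit (Dbar / pD / DIC):")
for source in ("trial", "registry", "gp", "hr", "total"):
    s = stats[source]
    print(f"  {source:<9} {s.d_bar:9.1f} {s.p_d:6.2f} {s.dic:9.1f}")

le = xs.life_expectancy_gain(draws, model, horizon=60.0)
print(f"\nmean survival, control:   {le.mean_control:6.1f} months")
print(f"mean survival, treatment: {le.mean_treatment:6.1f} months")
print(f"gain in life expectancy:  {le.gain_mean:6.1f} months "
      f"(95% CrI {le.gain_lo:.1f}; {le.gain_hi:.1f})")

t_late = np.array([6.0, 15.0, 30.0])
hr = np.median(
    [xs.hazard_ratio_curve(model, p, t_late) for p in draws.model_flat[::20]], axis=0
)
print("\nposterior median hazard ratio at years 6/15/30:",
      " ".join(f"{h:.2f}" for h in hr))
print("(the pseudo-data pull the late hazard ratio to 1: no treatment effect "
      "persists beyond year 6)")
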