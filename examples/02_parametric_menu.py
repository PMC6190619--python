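"""Fit a menu of standard parametric models to trial data alone and compare.

Models that fit the observed 5 years equally well (similar Dbar/DIC) can
imply very different life-expectancy gains, because the gain depends on the
extrapolated tail the trial never observes. This is the motivation for
bringing in external evidence.

A short chain is used here to keep the example quick; headline analyses
should use more steps (see the DIC column only as illustrative).
"""

import warnings

import extrasurv as xs
from extrasurv.workflow import run_model_menu

warnings.filterwarnings("ignore")

trial, _, _ = xs.generate_scenario(seed=1)

menu = (
    ("exponential", "PH"),
    ("weibull", "PH"),
    ("lognormal", "AFT"),
    ("lognormal", "FSEA"),
    ("gengamma", "AFT"),
)
table = run_model_menu(trial, menu, seed=7, n_steps=1500)
cols = ["model", "link", "d_bar", "dic", "gain_months", "gain_lo", "gain_hi"]
print(table[cols].round(1).to_string(index=False))
print(
    "\nEach row: posterior mean deviance, DIC, and the mean gain in life\n"
    "expectancy (months, with 95% credible interval) over a 60-year horizon.\n"
    "DIC differences under ~5 points do not distinguish models, yet the\n"
    "implied gains can differ several-fold."
)
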