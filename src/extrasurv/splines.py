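"""Restricted cubic splines for the log cumulative hazard as a function of log time.

The model follows the flexible parametric survival approach: the control arm's
log cumulative hazard is a natural (restricted) cubic spline in x = log t,

    log H0(t) = gamma0 . B(x; knots0)

and the treatment arm adds a second spline for the time-varying relative
effect,

    log H1(t) = gamma0 . B(x; knots0) + gamma_trt . B(x; knots_trt).

The basis is the knot-weighted truncated-power restricted cubic basis
{1, x, v_1(x), ..., v_{K-2}(x)} with

    v_j(x) = (x - k_j)^3_+  -  lam_j (x - k_min)^3_+  -  (1 - lam_j) (x - k_max)^3_+,
    lam_j  = (k_max - k_j) / (k_max - k_min),

so each spline has exactly as many coefficients as knots, is continuously
twice-differentiable inside the boundary knots and exactly linear outside
them. The linear tails are what make extrapolation beyond the data (here to
40+ years) well defined: the log cumulative hazard continues with constant
slope in log time.

Knot placement rule: boundary knots at the extreme ends of the data (the
smallest observed event time and the end of the external evidence horizon);
internal knots at the midpoint of each data segment on the log-time scale —
one inside the trial period and one between the end of the trial and the end
of the external data. The treatment-effect spline lives on the trial segment
with a single internal knot at its log-midpoint, allowing the hazard ratio
one turning point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ARM_CONTROL


def _trunc_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 3


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic basis matrix, shape (len(x), len(knots)).

    Columns: intercept, x, then one restricted cubic term per internal knot.
    With no internal knots (2 boundary knots) the basis is exactly {1, x}.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("basis abscissae must be finite")
    knots = np.asarray(knots, dtype=float)
    if knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("need >= 2 strictly increasing knots")
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        cols.append(
            _trunc_cube(x - kj) - lam * _trunc_cube(x - kmin) - (1.0 - lam) * _trunc_cube(x - kmax)
        )
    return np.column_stack(cols)


def rcs_basis_deriv(x, knots) -> np.ndarray:
    """Derivative of each basis column with respect to x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    kmin, kmax = knots[0], knots[-1]

    def dcube(u):
        return 3.0 * np.where(u > 0, u, 0.0) ** 2

    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        cols.append(dcube(x - kj) - lam * dcube(x - kmin) - (1.0 - lam) * dcube(x - kmax))
    return np.column_stack(cols)


def place_knots(
    trial_end: float,
    external_end: float,
    trial_times,
    n_internal_trial: int = 1,
    n_internal_external: int = 1,
    n_internal_treatment: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Knot locations (log-time) for the control and treatment-effect splines.

    Boundary knots sit at the extreme ends of the data: the smallest observed
    event time and the external-evidence horizon. Internal knots sit at the
    geometric midpoints (midpoints on the log scale) of the trial segment and
    of the extrapolation segment. Returns ``(control_knots, treatment_knots)``.
    """
    trial_times = np.asarray(trial_times, dtype=float)
    if trial_times.size == 0:
        raise ValueError("trial_times must be non-empty")
    if not trial_end < external_end:
        raise ValueError("trial_end must be < external_end")
    t_min = float(trial_times.min())
    if t_min <= 0:
        raise ValueError("observed times must be > 0")
    if t_min >= trial_end or np.isclose(t_min, external_end):
        raise ValueError("degenerate time range for knot placement")

    def log_mids(a, b, k):
        # k midpoints of (log a, log b): quantile positions 1/(k+1)..k/(k+1)
        return np.log(a) + (np.log(b) - np.log(a)) * np.arange(1, k + 1) / (k + 1)

    control = np.concatenate(
        [
            [np.log(t_min)],
            log_mids(t_min, trial_end, n_internal_trial),
            log_mids(trial_end, external_end, n_internal_external),
            [np.log(external_end)],
        ]
    )
    treatment = np.concatenate(
        [[np.log(t_min)], log_mids(t_min, trial_end, n_internal_treatment), [np.log(trial_end)]]
    )
    return control, treatment


@dataclass
class SplineSpec:
    """Knots (log-time) and coefficients for the two-spline survival model."""

    knots: np.ndarray
    knots_trt: np.ndarray
    gamma0: np.ndarray | None = None
    gamma_trt: np.ndarray | None = None

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.knots_trt = np.asarray(self.knots_trt, dtype=float)
        for k in (self.knots, self.knots_trt):
            if k.size < 2 or np.any(np.diff(k) <= 0):
                raise ValueError("knots must be >= 2 and strictly increasing")


class SplineTwoArmModel:
    """Two-arm flexible parametric model on the log-cumulative-hazard scale.

    Parameter vector: ``[gamma0 (one per control knot), gamma_trt (one per
    treatment knot)]``. Validity of a draw requires a strictly positive
    implied hazard, i.e. d(log H)/d(log t) > 0, on a log-spaced grid spanning
    the boundary knots for both arms.
    """

    def __init__(self, knots, knots_trt, n_valid_grid: int = 200):
        self.spec = SplineSpec(np.asarray(knots, float), np.asarray(knots_trt, float))
        self.knots = self.spec.knots
        self.knots_trt = self.spec.knots_trt
        self.n_gamma0 = len(self.knots)
        self.n_gamma_trt = len(self.knots_trt)
        self.n_params = self.n_gamma0 + self.n_gamma_trt
        self.param_names = tuple(f"gamma0_{i}" for i in range(self.n_gamma0)) + tuple(
            f"gamma_trt_{i}" for i in range(self.n_gamma_trt)
        )
        self._valid_x = np.linspace(self.knots[0], self.knots[-1], n_valid_grid)
        self._valid_B0d = rcs_basis_deriv(self._valid_x, self.knots)
        self._valid_B1d = rcs_basis_deriv(self._valid_x, self.knots_trt)

    @property
    def label(self) -> str:
        return "spline"

    def split(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        params = np.asarray(params, dtype=float)
        return params[: self.n_gamma0], params[self.n_gamma0 :]

    # -- evaluators --------------------------------------------------------
    def log_cum_hazard(self, params, t, arm):
        g0, gt = self.split(params)
        x = np.log(np.asarray(t, dtype=float))
        s = rcs_basis(x, self.knots) @ g0
        if arm != ARM_CONTROL:
            s = s + rcs_basis(x, self.knots_trt) @ gt
        return s

    def cum_hazard(self, params, t, arm):
        return np.exp(self.log_cum_hazard(params, t, arm))

    def survival(self, params, t, arm):
        return np.exp(-self.cum_hazard(params, t, arm))

    def ds_dx(self, params, t, arm):
        """Slope of log H in log time at t (must be > 0 for a valid hazard)."""
        g0, gt = self.split(params)
        x = np.log(np.asarray(t, dtype=float))
        d = rcs_basis_deriv(x, self.knots) @ g0
        if arm != ARM_CONTROL:
            d = d + rcs_basis_deriv(x, self.knots_trt) @ gt
        return d

    def log_hazard(self, params, t, arm):
        # h(t) = H(t) * s'(x) / t ; s'(x) <= 0 yields nan -> flagged invalid upstream
        t = np.asarray(t, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.log_cum_hazard(params, t, arm) + np.log(self.ds_dx(params, t, arm)) - np.log(t)

    def hazard(self, params, t, arm):
        return np.exp(self.log_hazard(params, t, arm))

    def valid(self, params: np.ndarray) -> bool:
        if not np.all(np.isfinite(params)):
            return False
        g0, gt = self.split(params)
        d0 = self._valid_B0d @ g0
        if np.any(d0 <= 0):
            return False
        return not np.any(d0 + self._valid_B1d @ gt <= 0)

    def initial_params(self, data) -> np.ndarray:
        """Least-squares fit of the control spline to the Nelson-Aalen estimate.

        The treatment spline starts at zero (null effect), which is always a
        valid draw whenever the control spline is.
        """
        from .nonparametric import nelson_aalen

        sub = data.subset(ARM_CONTROL)
        t, H = nelson_aalen(sub.time, sub.event)
        keep = H > 0
        if keep.sum() < self.n_gamma0:
            raise ValueError("too few distinct event times to initialize spline")
        B = rcs_basis(np.log(t[keep]), self.knots)
        g0, *_ = np.linalg.lstsq(B, np.log(H[keep]), rcond=None)
        params = np.concatenate([g0, np.zeros(self.n_gamma_trt)])
        if not self.valid(params):
            # fall back to the Weibull-like line through the data
            line = np.zeros(self.n_gamma0)
            line[0], line[1] = g0[0], max(abs(g0[1]), 0.5)
            params = np.concatenate([line, np.zeros(self.n_gamma_trt)])
        return params


def hazard_ratio_curve(model, params, t_grid) -> np.ndarray:
    """Element-wise hazard ratio h1(t)/h0(t) on a time grid.

    Works for any two-arm model; for the spline model this equals
    exp(gamma_trt . B_trt(x)) * (s0' + s_trt') / s0'.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    with np.errstate(all="ignore"):
        return np.exp(model.log_hazard(params, t_grid, 1) - model.log_hazard(params, t_grid, 0))
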