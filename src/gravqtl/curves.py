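"""Sigmoid and spline fits of gravitropism time courses.

A root gravitropism response (tip angle vs. time after 90-degree rotation)
is summarized by six mappable quantities:

* ``lambda`` (min) — lag phase before curvature develops,
* ``mu`` (deg/min) — maximum slope of the response,
* ``A`` (deg) — final steady-state angle (sigmoid asymptote),
* ``P`` (deg) — peak angle of a GCV smoothing spline through the data,
* overshoot ``P - A`` (deg) — excess of the transient peak over steady state,
* ``I`` (deg*min) — integral of the selected sigmoid over the window.

The sigmoid parameterizations follow the growth-curve convention in which
lambda is the intercept of the maximal-slope tangent with the time axis:

    logistic:  y(t) = A / (1 + exp(4*mu*(lambda - t)/A + 2))
    Gompertz:  y(t) = A * exp(-exp(mu*e*(lambda - t)/A + 1))

Both reach maximum slope mu (at y = A/2 and y = A/e respectively) and
asymptote A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

__all__ = [
    "SigmoidFit",
    "ResponseParameters",
    "logistic",
    "gompertz",
    "fit_logistic",
    "fit_gompertz",
    "select_model",
    "fit_spline",
    "extract_parameters",
    "fit_line_parameters",
]


def logistic(t, A, mu, lam):
    t = np.asarray(t, dtype=float)
    z = np.clip(4.0 * mu * (lam - t) / A + 2.0, -700, 700)
    return A / (1.0 + np.exp(z))


def gompertz(t, A, mu, lam):
    t = np.asarray(t, dtype=float)
    z = np.clip(mu * math.e * (lam - t) / A + 1.0, -700, 700)
    return A * np.exp(-np.exp(z))


_MODELS = {"logistic": logistic, "gompertz": gompertz}


@dataclass
class SigmoidFit:
    model: str
    A: float
    mu: float
    lam: float
    rss: float
    aic: float
    converged: bool

    def __call__(self, t):
        return _MODELS[self.model](t, self.A, self.mu, self.lam)


@dataclass
class ResponseParameters:
    """The six mappable response quantities for one line."""

    lam: float
    mu: float
    A: float
    P: float
    overshoot: float
    I: float
    model: str
    t_P: float
    rss: float
    converged: bool


def _series_arrays(series):
    """Accept a TipAngleSeries or a (times, angles) pair; drop missing."""
    if hasattr(series, "times"):
        t = np.asarray(series.times, dtype=float)
        y = np.asarray(series.angles, dtype=float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    keep = np.isfinite(y)
    return t[keep], y[keep]


def _initial_guess(t, y):
    A0 = float(np.max(y))
    if A0 <= 0:
        A0 = max(float(np.ptp(y)), 1.0)
    slopes = np.gradient(y, t)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes[k]), 1e-3)
    lam0 = max(float(t[k] - y[k] / mu0), 0.0)
    return A0, mu0, lam0


def _fit_sigmoid(series, model: str, restarts: int = 5, seed: int = 0) -> SigmoidFit:
    t, y = _series_arrays(series)
    if t.size < 6:
        raise ValueError("need at least 6 time points to fit a sigmoid")
    if np.ptp(y) == 0.0:
        raise ValueError("constant series cannot be fit")
    f = _MODELS[model]
    theta0 = np.array(_initial_guess(t, y))
    span = max(float(t[-1] - t[0]), 1.0)
    lb = np.array([1e-6, 1e-6, -span])
    ub = np.array([np.inf, np.inf, t[-1]])
    rng = np.random.default_rng(seed)

    def resid(theta):
        return f(t, *theta) - y

    best = None
    start = np.clip(theta0, lb, ub)
    for attempt in range(restarts + 1):
        try:
            sol = least_squares(resid, start, bounds=(lb, ub), ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            sol = None
        if sol is not None:
            rss = 2.0 * sol.cost
            if best is None or rss < best[0]:
                best = (rss, sol)
            if sol.success:
                break
        start = np.clip(theta0 * rng.lognormal(0.0, 0.3, size=3), lb, ub)
    if best is None:
        return SigmoidFit(model, *theta0, rss=float("inf"), aic=float("inf"), converged=False)
    rss, sol = best
    n = t.size
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * 3
    A, mu, lam = (float(v) for v in sol.x)
    return SigmoidFit(model, A, mu, lam, rss=float(rss), aic=float(aic), converged=bool(sol.success))


def fit_logistic(series, restarts: int = 5, seed: int = 0) -> SigmoidFit:
    """Nonlinear least-squares logistic fit (asymptote A, max slope mu, lag lambda)."""
    return _fit_sigmoid(series, "logistic", restarts, seed)


def fit_gompertz(series, restarts: int = 5, seed: int = 0) -> SigmoidFit:
    """Nonlinear least-squares Gompertz fit (asymmetric sigmoid, max slope at A/e)."""
    return _fit_sigmoid(series, "gompertz", restarts, seed)


def select_model(fit_log: SigmoidFit | None, fit_gom: SigmoidFit | None) -> SigmoidFit:
    """Pick the better of the two sigmoid fits by AIC; ties go to logistic.

    With equal parameter counts the AIC rule reduces to lower RSS.  If only
    one fit converged it is selected; if neither did, raises ValueError.
    """
    ok = [f for f in (fit_log, fit_gom) if f is not None and f.converged]
    if not ok:
        raise ValueError("neither sigmoid fit converged")
    if len(ok) == 1:
        return ok[0]
    if fit_log.aic <= fit_gom.aic:  # tie -> logistic
        return fit_log
    return fit_gom


def fit_spline(series, eval_step: float = 0.1):
    """GCV cubic smoothing spline; returns (P, t_P, I_spline).

    P is the maximum of the spline on an ``eval_step``-minute grid over the
    observation window, t_P its argmax, I_spline the trapezoid integral of
    the spline over the window.  A constant series short-circuits to
    P = constant at the first time.
    """
    t, y = _series_arrays(series)
    if np.ptp(y) == 0.0:
        return float(y[0]), float(t[0]), float(y[0] * (t[-1] - t[0]))
    if t.size < 8:
        raise ValueError("need at least 8 time points for spline fitting")
    spl = make_smoothing_spline(t, y)  # lam chosen by GCV
    grid = np.arange(t[0], t[-1] + eval_step / 2, eval_step)
    vals = spl(grid)
    k = int(np.argmax(vals))
    I_spline = float(np.trapezoid(vals, grid))
    return float(vals[k]), float(grid[k]), I_spline


def extract_parameters(fit: SigmoidFit, spline_result, window, eval_step: float = 0.1) -> ResponseParameters:
    """Combine a selected sigmoid fit and a spline peak into the trait set.

    overshoot = P - A, left unclipped (slightly negative values are kept);
    I is the composite-trapezoid integral of the selected sigmoid on an
    ``eval_step``-minute grid over ``window`` = (t_first, t_last).
    """
    if not fit.converged:
        raise ValueError("cannot extract parameters from a non-converged fit")
    P, t_P, _ = spline_result
    t0, t1 = (float(w) for w in window)
    grid = np.arange(t0, t1 + eval_step / 2, eval_step)
    I = float(np.trapezoid(fit(grid), grid))
    return ResponseParameters(
        lam=fit.lam,
        mu=fit.mu,
        A=fit.A,
        P=P,
        overshoot=P - fit.A,
        I=I,
        model=fit.model,
        t_P=t_P,
        rss=fit.rss,
        converged=fit.converged,
    )


def fit_line_parameters(series, seed: int = 0) -> ResponseParameters | None:
    """Full per-line pipeline: both sigmoids, model selection, spline, traits.

    Returns None when neither sigmoid converges (the line is flagged and its
    parameters left missing upstream).
    """
    t, y = _series_arrays(series)
    try:
        fl = fit_logistic((t, y), seed=seed)
    except ValueError:
        fl = None
    try:
        fg = fit_gompertz((t, y), seed=seed)
    except ValueError:
        fg = None
    try:
        chosen = select_model(fl, fg)
    except ValueError:
        return None
    sp = fit_spline((t, y))
    return extract_parameters(chosen, sp, (t[0], t[-1]))
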