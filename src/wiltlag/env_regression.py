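"""Regression of per-day lag-correlation summaries on daily environment means.

Five regression families relate a per-day response (R_max or l_max) to the
daily 09:00-19:00 arithmetic mean of PPFD or VPD:

    linear       y = a x + b
    quadratic    y = a x^2 + b x + c
    piecewise    y = b1 + a1 x (x <= tau); b1 + a1 tau + a2 (x - tau) (x > tau)
                 continuous at the fitted breakpoint tau
    log          y = a ln(x) + b
    exponential  y = a exp(b x) + c

Model selection maximises raw R^2 = 1 - SS_res/SS_tot (exact ties go to the
family with fewer parameters); significance is an overall F test on R^2 with
k = the number of predictor-side parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "FitError",
    "FAMILIES",
    "mean_env",
    "fit_family",
    "select_model",
    "regression_pvalue",
]

ENV_WINDOW = (time(9, 0), time(19, 0))

FAMILIES = ("linear", "quadratic", "piecewise_linear", "log", "exponential")

#: total fitted parameters per family (includes intercept-like terms)
N_PARAMS = {"linear": 2, "log": 2, "quadratic": 3, "exponential": 3, "piecewise_linear": 4}
#: predictor-side parameters (k of the overall F test)
N_PREDICTOR_PARAMS = {
    "linear": 1,
    "log": 1,
    "quadratic": 2,
    "exponential": 2,
    "piecewise_linear": 3,
}


class FitError(ValueError):
    """A regression family failed on the given data (reported, not fatal)."""


@dataclass
class FitResult:
    family: str
    params: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    p_value: float = float("nan")
    n: int = 0
    adj_r_squared: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return _predict(self.family, self.params, np.asarray(x, dtype=float))


def mean_env(env: pd.DataFrame, date, window: tuple[time, time] = ENV_WINDOW) -> dict:
    """Arithmetic daily means of PPFD and VPD over the half-open window [start, end).

    Missing minutes are excluded; the fraction of the window covered is
    reported as ``coverage``.  Raises if the window holds zero samples.
    """
    date = pd.Timestamp(date).date()
    day = env[np.asarray(env.index.date) == date]
    tod = day.index.time
    sel = day[(tod >= window[0]) & (tod < window[1])]
    expected = (window[1].hour * 60 + window[1].minute) - (
        window[0].hour * 60 + window[0].minute
    )
    if sel.empty:
        raise ValueError(f"no environment samples on {date} within {window}")
    return {
        "date": date,
        "mean_ppfd": float(sel["ppfd"].mean()),
        "mean_vpd": float(sel["vpd"].mean()),
        "coverage": len(sel) / expected,
    }


def _predict(family: str, params: dict, x: np.ndarray) -> np.ndarray:
    if family == "linear":
        return params["a"] * x + params["b"]
    if family == "quadratic":
        return params["a"] * x**2 + params["b"] * x + params["c"]
    if family == "log":
        return params["a"] * np.log(x) + params["b"]
    if family == "exponential":
        return params["a"] * np.exp(params["b"] * x) + params["c"]
    if family == "piecewise_linear":
        a1, b1, a2, tau = params["a1"], params["b1"], params["a2"], params["tau"]
        return np.where(x <= tau, b1 + a1 * x, b1 + a1 * tau + a2 * (x - tau))
    raise ValueError(f"unknown family {family!r}")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise FitError("zero total variance: R^2 undefined")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def _piecewise_ssr(x: np.ndarray, y: np.ndarray, tau: float):
    """Closed-form continuous two-segment LS at a fixed breakpoint."""
    design = np.column_stack([np.ones_like(x), np.minimum(x, tau), np.maximum(x - tau, 0.0)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def _fit_piecewise(x: np.ndarray, y: np.ndarray) -> dict:
    xs = np.unique(x)
    if len(xs) < 4:
        raise FitError("piecewise fit needs at least 4 distinct x values")
    # candidate breakpoints: midpoints between consecutive interior x values
    mids = (xs[1:] + xs[:-1]) / 2.0
    candidates = mids[1:-1] if len(mids) > 2 else mids
    ssr = np.array([_piecewise_ssr(x, y, t)[0] for t in candidates])
    best = int(np.argmin(ssr))
    lo = candidates[max(0, best - 1)]
    hi = candidates[min(len(candidates) - 1, best + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: _piecewise_ssr(x, y, t)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        tau = float(res.x)
        if _piecewise_ssr(x, y, tau)[0] > ssr[best]:
            tau = float(candidates[best])
    else:
        tau = float(candidates[best])
    _, coef = _piecewise_ssr(x, y, tau)
    return {"b1": float(coef[0]), "a1": float(coef[1]), "a2": float(coef[2]), "tau": tau}


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> dict:
    span = y.max() - y.min()
    increasing = np.corrcoef(x, y)[0, 1] >= 0
    c0 = y.min() - 0.05 * span if increasing else y.max() + 0.05 * span
    shifted = y - c0
    sign = 1.0 if shifted.mean() >= 0 else -1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        logs = np.log(np.clip(sign * shifted, 1e-12, None))
    b0, loga0 = np.polyfit(x, logs, 1)
    p0 = [sign * np.exp(loga0), b0, c0]
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, a, b, c: a * np.exp(b * xx) + c, x, y, p0=p0, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as err:
        raise FitError(f"exponential fit did not converge: {err}") from err
    if not np.all(np.isfinite(popt)):
        raise FitError("exponential fit produced non-finite parameters")
    return {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])}


def fit_family(x, y, family: str) -> FitResult:
    """Least-squares fit of one regression family; raises FitError on failure."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    n = len(x)
    if n < N_PARAMS[family] + 2:
        raise FitError(f"{family}: need at least {N_PARAMS[family] + 2} points, got {n}")
    if family == "log" and np.any(x <= 0):
        raise FitError("log family requires strictly positive x")
    if np.all(y == y[0]):
        raise FitError("zero response variance: R^2 undefined")

    if family == "linear":
        a, b = np.polyfit(x, y, 1)
        params = {"a": float(a), "b": float(b)}
    elif family == "quadratic":
        a, b, c = np.polyfit(x, y, 2)
        params = {"a": float(a), "b": float(b), "c": float(c)}
    elif family == "log":
        a, b = np.polyfit(np.log(x), y, 1)
        params = {"a": float(a), "b": float(b)}
    elif family == "exponential":
        params = _fit_exponential(x, y)
    else:
        params = _fit_piecewise(x, y)

    yhat = _predict(family, params, x)
    r2 = _r2(y, yhat)
    k = N_PREDICTOR_PARAMS[family]
    result = FitResult(
        family=family,
        params=params,
        r_squared=r2,
        n=n,
        adj_r_squared=1 - (1 - r2) * (n - 1) / (n - k - 1) if n > k + 1 else float("nan"),
    )
    result.p_value = regression_pvalue(result)
    return result


def regression_pvalue(fit: FitResult) -> float:
    """Overall F-test p-value for a fitted family.

    F = (R^2/k) / ((1-R^2)/(n-k-1)) with k predictor-side parameters (the
    piecewise breakpoint counts); R^2 = 0 gives p = 1, R^2 -> 1 gives p -> 0.
    """
    k = N_PREDICTOR_PARAMS[fit.family]
    n = fit.n
    if n <= k + 1:
        raise ValueError("p-value undefined: too few points for the F test")
    r2 = min(max(fit.r_squared, 0.0), 1.0)
    if r2 >= 1.0:
        return 0.0
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return float(stats.f.sf(f, k, n - k - 1))


def select_model(x, y, families=FAMILIES) -> FitResult:
    """Fit every family and return the one with maximal raw R^2.

    Ties (within 1e-9) are broken toward the family with fewer parameters;
    families that fail to fit are excluded.  Raises FitError if none succeed.
    """
    fits: list[FitResult] = []
    for family in families:
        try:
            fits.append(fit_family(x, y, family))
        except FitError:
            continue
    if not fits:
        raise FitError("all regression families failed")
    best_r2 = max(f.r_squared for f in fits)
    contenders = [f for f in fits if f.r_squared >= best_r2 - 1e-9]
    return min(contenders, key=lambda f: N_PARAMS[f.family])
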