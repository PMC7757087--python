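"""Least-squares fitting of growth curves and the ISRP goodness-of-fit metric.

Three candidate models are fitted to cumulative (time, size) series by
unweighted nonlinear least squares with Latin-hypercube multi-start:

- ``gpd``      N(t) = y exp{A b [1 - (b/(a t + b))^(1/a)]}   params (y, A, a, b)
- ``gompertz`` N(t) = y exp{(alpha/beta)(1 - e^{-beta t})}   params (y, alpha, beta)
- ``logistic`` N(t) = C / (1 + ((C - y)/y) e^{-r t})         params (y, r, C)

The interval-specific rate parameter (ISRP) re-estimates each model's
constant growth parameter (A, alpha or r) from every pair of consecutive
observations, holding the remaining fitted parameters fixed; on data that
follow the fitted model exactly each interval estimate equals the constant,
so the Euclidean distance d2 between the ISRP series and the constant
measures lack of fit on the rate scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import DomainError, FitError, ParameterError
from .growth import GPDParams, classify_case, gpd_curve, reference_curve, ReferenceModel

__all__ = [
    "MODEL_KINDS",
    "TimeSeries",
    "FitResult",
    "ISRPSeries",
    "moving_mean3",
    "predict_curve",
    "fit_least_squares",
    "ssr",
    "isrp",
    "d2_distance",
    "one_step_prediction",
]

MODEL_KINDS = ("gpd", "gompertz", "logistic")

_N_PARAMS = {"gpd": 4, "gompertz": 3, "logistic": 3}
_PARAM_NAMES = {
    "gpd": ("y", "A", "a", "b"),
    "gompertz": ("y", "alpha", "beta"),
    "logistic": ("y", "r", "C"),
}


@dataclass(frozen=True)
class TimeSeries:
    """Ordered (time, value) observations."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ParameterError("times and values must be 1-D of equal length")
        if len(times) < 2:
            raise ParameterError("a time series needs at least 2 observations")
        if not np.all(np.diff(times) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(values < 0):
            raise ParameterError("values must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    kind: str
    params: tuple
    ssr: float
    n_obs: int
    converged: bool
    starts_used: int

    def as_gpd_params(self) -> GPDParams:
        if self.kind != "gpd":
            raise ParameterError(f"fit is for kind {self.kind!r}, not gpd")
        return GPDParams(*self.params)


@dataclass(frozen=True)
class ISRPSeries:
    """Per-interval estimates of the constant growth parameter."""

    interval_estimates: np.ndarray
    reference_rate: float
    d2: float = field(init=False)

    def __post_init__(self) -> None:
        est = np.asarray(self.interval_estimates, dtype=float)
        object.__setattr__(self, "interval_estimates", est)
        if est.size == 0:
            raise ParameterError("ISRP needs at least one interval")
        object.__setattr__(
            self, "d2", float(np.linalg.norm(est - self.reference_rate))
        )


def moving_mean3(s: TimeSeries) -> TimeSeries:
    """3-point mobile mean ``(n(i) + n(i+1) + n(i+2)) / 3``.

    Smooths reporting noise in daily surveillance counts; the output has
    length ``n - 2`` with times aligned to the first index of each window.
    """
    if len(s) < 3:
        raise ParameterError("moving_mean3 needs at least 3 observations")
    v = s.values
    smoothed = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return TimeSeries(s.times[:-2].copy(), smoothed, label=s.label)


def _check_kind(kind: str) -> None:
    if kind not in MODEL_KINDS:
        raise ParameterError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def predict_curve(kind: str, params: Sequence[float], t) -> np.ndarray:
    """Evaluate the named model at times ``t`` (strict domain checks)."""
    _check_kind(kind)
    t = np.asarray(t, dtype=float)
    if kind == "gpd":
        return np.asarray(gpd_curve(t, GPDParams(*params)))
    if kind == "gompertz":
        return np.asarray(reference_curve(t, ReferenceModel("gompertz", tuple(params))))
    return np.asarray(reference_curve(t, ReferenceModel("logistic", tuple(params))))


def _predict_relaxed(kind: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Model evaluation used inside the optimiser: the GPD curve is
    extended continuously past a case-(iv) endpoint by clamping ``a t + b``
    at a tiny positive value (the curve then sits at its limit C), so the
    residual function stays finite and smooth near the domain boundary."""
    if kind == "gpd":
        y, A, a, b = params
        denom = np.maximum(a * t + b, 1e-12)
        return y * np.exp(A * b * (1.0 - (b / denom) ** (1.0 / a)))
    if kind == "gompertz":
        y, alpha, beta = params
        return y * np.exp(alpha / beta * (1.0 - np.exp(-beta * t)))
    y, r, C = params
    return C / (1.0 + (C - y) / y * np.exp(-r * t))


def _start_boxes(kind: str, s: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven multi-start boxes (lower, upper) per parameter."""
    positive = s.values[s.values > 0]
    vmin = float(positive.min()) if positive.size else 1.0
    vmax = float(np.max(s.values))
    eps = 1e-8
    if kind == "gpd":
        lo = np.array([eps, eps, -0.99, eps])
        hi = np.array([2.0 * vmin, 20.0, 20.0, 50.0])
    elif kind == "gompertz":
        lo = np.array([eps, eps, eps])
        hi = np.array([2.0 * vmin, 20.0, 20.0])
    else:
        lo = np.array([eps, eps, vmax * (1.0 + 1e-6)])
        hi = np.array([2.0 * vmin, 20.0, 100.0 * vmax])
    return lo, hi


def fit_least_squares(
    s: TimeSeries,
    kind: str,
    starts: int = 64,
    seed: Optional[int] = None,
) -> FitResult:
    """Multi-start nonlinear least squares for one model kind.

    ``starts`` Latin-hypercube points are drawn from data-driven boxes
    (deterministic under ``seed``) and each is refined with a bounded
    trust-region least-squares solve; the best local minimum is returned.
    """
    _check_kind(kind)
    n_par = _N_PARAMS[kind]
    if len(s) < n_par + 1:
        raise ParameterError(
            f"need at least {n_par + 1} observations to fit {kind!r}"
        )
    lo, hi = _start_boxes(kind, s)
    sampler = qmc.LatinHypercube(d=n_par, seed=seed)
    x0s = lo + sampler.random(starts) * (hi - lo)
    t, v = s.times, s.values

    def residuals(x: np.ndarray) -> np.ndarray:
        return _predict_relaxed(kind, x, t) - v

    best_ssr, best_x, n_ok = math.inf, None, 0
    for x0 in x0s:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        n_ok += 1
        this_ssr = float(np.sum(res.fun ** 2))
        if this_ssr < best_ssr:
            best_ssr, best_x = this_ssr, res.x
    if best_x is None:
        raise FitError(
            f"none of the {starts} starts converged for kind {kind!r} "
            f"(n_obs={len(s)}, boxes lo={lo!r}, hi={hi!r})"
        )
    return FitResult(
        kind=kind,
        params=tuple(float(x) for x in best_x),
        ssr=best_ssr,
        n_obs=len(s),
        converged=True,
        starts_used=n_ok,
    )


def ssr(s: TimeSeries, kind: str, params: Sequence[float]) -> float:
    """Sum of squared residuals of the model at the given parameters."""
    pred = predict_curve(kind, params, s.times)
    return float(np.sum((s.values - pred) ** 2))


def isrp(s: TimeSeries, kind: str, params: Sequence[float]) -> ISRPSeries:
    """Interval-specific rate parameter series for the fitted model.

    For each pair of consecutive *observed* values ``(n_i, n_{i+1})`` at
    times ``(t_i, t_{i+1})`` the constant growth parameter is re-estimated
    by inverting the model's increment, holding the remaining parameters at
    their fitted values:

    - gompertz: ``alpha_i = beta * log(n_{i+1}/n_i) /
      (e^{-beta t_i} - e^{-beta t_{i+1}})``
    - gpd: ``A_i = log(n_{i+1}/n_i) / (b [ (b/(a t_i + b))^{1/a} -
      (b/(a t_{i+1} + b))^{1/a} ])``
    - logistic: ``r_i = log[ (C/n_i - 1) / (C/n_{i+1} - 1) ] /
      (t_{i+1} - t_i)``

    Each estimator is exact (returns the constant) on data generated by the
    fitted model.
    """
    _check_kind(kind)
    if np.any(s.values <= 0):
        raise DomainError("ISRP needs strictly positive values")
    t0, t1 = s.times[:-1], s.times[1:]
    n0, n1 = s.values[:-1], s.values[1:]
    log_ratio = np.log(n1 / n0)
    if kind == "gompertz":
        y, alpha, beta = params
        est = beta * log_ratio / (np.exp(-beta * t0) - np.exp(-beta * t1))
        ref = float(alpha)
    elif kind == "gpd":
        p = GPDParams(*params)

        def w(tt: np.ndarray) -> np.ndarray:
            # for a < 0 the power term (b/(a t + b))^(1/a) has limit 0 at the
            # saturation endpoint b/|a|; observations at or past it (a fitted
            # curve may saturate before the last data point) use that limit,
            # consistent with the constant-C extension used in fitting
            denom = p.a * tt + p.b
            with np.errstate(divide="ignore"):
                out = np.where(denom > 0,
                               (p.b / np.where(denom > 0, denom, 1.0)) ** (1.0 / p.a),
                               0.0)
            return out

        est = log_ratio / (p.b * (w(t0) - w(t1)))
        ref = float(p.A)
    else:
        y, r, C = params
        if np.any(s.values >= C):
            raise DomainError("logistic ISRP needs all values below C")
        est = np.log((C / n0 - 1.0) / (C / n1 - 1.0)) / (t1 - t0)
        ref = float(r)
    return ISRPSeries(interval_estimates=est, reference_rate=ref)


def d2_distance(series: ISRPSeries) -> float:
    """Euclidean distance between the ISRP series and the constant
    parameter (unnormalised over the ``n-1`` intervals)."""
    return series.d2


def one_step_prediction(
    s: TimeSeries,
    kind: str,
    horizon: int,
    starts: int = 64,
    seed: Optional[int] = None,
) -> np.ndarray:
    """One-step-ahead predictions for the last ``horizon`` observations.

    For each target index ``i`` the model is refitted to observations
    ``0..i-1`` only and then evaluated at ``t_i``; this mimics day-ahead
    forecasting of a running epidemic or defect count.
    """
    _check_kind(kind)
    n = len(s)
    n_par = _N_PARAMS[kind]
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")
    if n - horizon < n_par + 1:
        raise ParameterError(
            f"prefix too short: need {n_par + 1} points before the first target"
        )
    preds = np.empty(horizon)
    for j, i in enumerate(range(n - horizon, n)):
        prefix = TimeSeries(s.times[:i], s.values[:i], label=s.label)
        fit = fit_least_squares(prefix, kind, starts=starts, seed=seed)
        preds[j] = _predict_relaxed(
            kind, np.asarray(fit.params, dtype=float), np.asarray([s.times[i]])
        )[0]
    return preds
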