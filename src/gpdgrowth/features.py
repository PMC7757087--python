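"""Analytic features of the GPD growth curve.

When ``A*b > a+1`` the curve is sigmoidal and admits an inflection point

    t_I = (b/a) [ (A b/(a+1))^a - 1 ],      N(t_I) = C e^{-(a+1)},

a maximum specific growth rate mu (the slope of the tangent at t_I), and a
lag time lambda (the t-axis intercept of that tangent) that summarises the
initial slow phase.  When ``A*b < a+1`` the curve is concave from the start
and these features are absent.  The module also inverts the curve for
threshold-crossing times and implements the first-order sensitivity of the
curve to each of the four parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, FeatureUndefinedError, NumericError, ParameterError
from .growth import (
    GOMPERTZ_LIMIT_SHAPE,
    GPDParams,
    _signed_power,
    classify_case,
    gpd_curve,
    gpd_rate,
)

__all__ = [
    "TangentLine",
    "SensitivityReport",
    "second_derivative",
    "inflection_time",
    "boundary_inflection_time",
    "inflection_value",
    "max_specific_growth_rate",
    "tangent_and_lag",
    "threshold_time",
    "sensitivity",
]


@dataclass(frozen=True)
class TangentLine:
    """Tangent to the curve at the inflection point: ``n(t) = slope*t +
    intercept``; ``lag_time`` is its t-axis intercept (the lag phase
    duration, negative when the curve takes off immediately)."""

    slope: float
    intercept: float
    lag_time: float


@dataclass(frozen=True)
class SensitivityReport:
    """First-order effect of perturbing one parameter by ``epsilon``.

    ``delta_curve(t)`` returns the first-order change
    ``N^{nu+eps}(t) - N^{nu}(t)`` (a function of time); ``sign_profile``
    describes the sign of that change over the domain; ``sign_change_time``
    is the time where the sign flips (only for parameter ``b`` in case ii,
    else ``None``).
    """

    parameter: Literal["y", "A", "a", "b"]
    epsilon: float
    delta_curve: Callable[[np.ndarray], np.ndarray]
    sign_profile: str
    sign_change_time: Optional[float] = None


def _require_sigmoidal(p: GPDParams) -> None:
    if p.A * p.b <= p.a + 1.0:
        raise FeatureUndefinedError(
            f"A*b = {p.A * p.b:g} <= a+1 = {p.a + 1.0:g}: the curve has no "
            "interior inflection and mu/lag are undefined"
        )


def second_derivative(t, p: GPDParams):
    """Closed-form second derivative of the curve.

    ``N''(t) = A N(t) u^{1/a+1} [ A u^{1/a+1} - (a+1)/(a t + b) ]`` with
    ``u = b/(a t + b)``; its unique interior root (when ``A b > a+1``) is
    the inflection time.
    """
    t = np.asarray(t, dtype=float)
    N = gpd_curve(t, p)
    xi = gpd_rate(t, p)
    if abs(p.a) < GOMPERTZ_LIMIT_SHAPE:
        bracket = xi - 1.0 / p.b
    else:
        bracket = xi - (p.a + 1.0) / (p.a * t + p.b)
    out = N * xi * bracket
    return out if np.ndim(out) else float(out)


def inflection_time(p: GPDParams) -> Optional[float]:
    """Interior inflection time ``t_I``, or ``None`` when ``A b <= a+1``.

    Case (ii) curves additionally change concavity at ``b/|a|``; see
    :func:`boundary_inflection_time`.
    """
    Ab = p.A * p.b
    if Ab <= p.a + 1.0:
        return None
    if abs(p.a) < GOMPERTZ_LIMIT_SHAPE:
        return p.b * math.log(Ab)
    return (p.b / p.a) * ((Ab / (p.a + 1.0)) ** p.a - 1.0)


def boundary_inflection_time(p: GPDParams) -> Optional[float]:
    """The concavity change at ``t = b/|a|`` exhibited by case-(ii) curves
    (a boundary inflection across the exponent-branch change, present for
    any ``A b``), or ``None`` for the other cases."""
    if classify_case(p).label != "ii":
        return None
    return p.b / abs(p.a)


def inflection_value(p: GPDParams) -> float:
    """Population size at the inflection, ``N(t_I) = C e^{-(a+1)}``."""
    _require_sigmoidal(p)
    return p.carrying_capacity * math.exp(-(p.a + 1.0))


def max_specific_growth_rate(p: GPDParams) -> float:
    """Maximum specific growth rate
    ``mu = A y ((a+1)/(A b))^{1+a} e^{A b - (a+1)}`` (= N'(t_I))."""
    _require_sigmoidal(p)
    Ab = p.A * p.b
    return p.A * p.y * ((p.a + 1.0) / Ab) ** (1.0 + p.a) * math.exp(Ab - (p.a + 1.0))


def tangent_and_lag(p: GPDParams) -> TangentLine:
    """Tangent at the inflection point and the lag time.

    ``lag = (b/a)[(A b/(a+1))^a / (a+1) - 1]``; it is positive exactly when
    ``A b > (a+1)^{1/a + 1}``.
    """
    _require_sigmoidal(p)
    mu = max_specific_growth_rate(p)
    Ab = p.A * p.b
    a = p.a
    if abs(a) < GOMPERTZ_LIMIT_SHAPE:
        # Gompertz limit: t_I = b log(Ab), N(t_I) = C/e, slope mu
        t_i = p.b * math.log(Ab)
        intercept = inflection_value(p) - mu * t_i
    else:
        intercept = (
            p.y
            * math.exp(Ab - a - 1.0)
            * (((a + 1.0) / Ab) ** a * (a + 1.0) / a - 1.0 / a)
        )
    lag = -intercept / mu
    return TangentLine(slope=mu, intercept=intercept, lag_time=lag)


def threshold_time(
    p: GPDParams,
    mode: Literal["absolute", "fraction_of_C", "fraction_of_inflection"],
    value: float,
) -> float:
    """Time at which the curve crosses a threshold.

    ``mode="absolute"``: the crossing time of level ``S = value`` with
    ``y < S < C``; ``mode="fraction_of_C"``: of ``p*C`` with
    ``e^{-Ab} < p < 1``; ``mode="fraction_of_inflection"``: of
    ``p*N(t_I)`` with ``e^{-Ab+a+1} < p < 1`` (requires ``A b > a+1``).
    Inverse of :func:`gpdgrowth.growth.gpd_curve` on the increasing branch.
    """
    Ab = p.A * p.b
    if mode == "absolute":
        S = value
        if not (S > p.y and math.log(S / p.y) < Ab):
            raise DomainError(
                f"absolute threshold must lie in (y, C) = "
                f"({p.y:g}, {p.carrying_capacity:g}), got {S!r}"
            )
        w = 1.0 - math.log(S / p.y) / Ab
    elif mode == "fraction_of_C":
        frac = value
        lo = math.exp(-Ab)
        if not (lo < frac < 1.0):
            raise DomainError(
                f"fraction of C must lie in (e^(-A b), 1) = ({lo:g}, 1), got {frac!r}"
            )
        w = -math.log(frac) / Ab
    elif mode == "fraction_of_inflection":
        _require_sigmoidal(p)
        frac = value
        lo = math.exp(-Ab + p.a + 1.0)
        if not (lo < frac <= 1.0):
            raise DomainError(
                f"fraction of N(t_I) must lie in (e^(-A b + a + 1), 1] = "
                f"({lo:g}, 1], got {frac!r}"
            )
        w = -(math.log(frac) - p.a - 1.0) / Ab
    else:
        raise ParameterError(f"unknown threshold mode {mode!r}")
    if abs(p.a) < GOMPERTZ_LIMIT_SHAPE:
        return -p.b * math.log(w)
    return (p.b / p.a) * (w ** (-p.a) - 1.0)


def _sensitivity_b_sign_change(p: GPDParams) -> float:
    """Locate t-bar > b/|a| where the first-order effect of b flips sign
    (case ii only), by bracketing + Brent bisection to 1e-8."""
    case = classify_case(p)
    if case.label != "ii":
        raise FeatureUndefinedError("the sign change exists only in case (ii)")
    m = round(1.0 / abs(p.a))

    def h(t: float) -> float:
        u = p.b / (p.a * t + p.b)
        upow = float(_signed_power(u, -m))
        return 1.0 - upow * (1.0 + t / (p.a * t + p.b))

    t_lo = p.b / abs(p.a) * 1.0000001
    t_hi = t_lo * 2.0
    for _ in range(200):
        if h(t_hi) < 0:
            break
        t_lo, t_hi = t_hi, t_hi * 2.0
    else:
        raise NumericError("failed to bracket the sensitivity sign change")
    return float(brentq(h, t_lo, t_hi, xtol=1e-8))


def sensitivity(p: GPDParams, parameter: str, epsilon: float) -> SensitivityReport:
    """First-order (Taylor) effect of ``parameter -> parameter + epsilon``.

    Signs: increasing ``y`` or ``A`` raises the curve everywhere; increasing
    ``a`` lowers it everywhere; increasing ``b`` raises it in cases (i),
    (iii), (iv) while in case (ii) the effect is positive up to some
    ``t-bar > b/|a|`` and negative afterwards (located numerically).
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    if parameter not in ("y", "A", "a", "b"):
        raise ParameterError(f"unknown parameter {parameter!r}")
    perturbed = {
        "y": GPDParams(p.y + epsilon, p.A, p.a, p.b),
        "A": GPDParams(p.y, p.A + epsilon, p.a, p.b),
        "a": GPDParams(p.y, p.A, p.a + epsilon, p.b),
        "b": GPDParams(p.y, p.A, p.a, p.b + epsilon),
    }[parameter]
    # the perturbation must not change the qualitative case
    if parameter in ("a", "b") and classify_case(perturbed).label != classify_case(p).label:
        raise ParameterError(
            "epsilon moves the parameters across a case boundary; "
            "use a smaller perturbation"
        )
    case = classify_case(p)

    def _core(t: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
        t = np.asarray(t, dtype=float)
        N = np.asarray(gpd_curve(t, p))
        denom = p.a * t + p.b
        u = p.b / denom
        if case.label in ("ii", "iii"):
            upow = _signed_power(u, -round(1.0 / abs(p.a)))
        else:
            upow = u ** (1.0 / p.a)
        return t, N, (denom, u, upow)

    if parameter == "y":
        def delta(t):
            _, N, _ = _core(t)
            return epsilon * N / p.y
        profile = "positive for all t > 0"
        t_bar = None
    elif parameter == "A":
        def delta(t):
            _, N, (_, _, upow) = _core(t)
            return epsilon * N * p.b * (1.0 - upow)
        profile = "positive for all t > 0"
        t_bar = None
    elif parameter == "a":
        def delta(t):
            t, N, (denom, u, _) = _core(t)
            u1 = u ** (1.0 / p.a + 1.0)
            return (
                epsilon
                * N
                * (p.A / p.a ** 2)
                * u1
                * (p.a * t + denom * np.log(u))
            )
        profile = "negative for all t > 0 in the domain"
        t_bar = None
    else:  # b
        def delta(t):
            t, N, (denom, _, upow) = _core(t)
            return epsilon * N * p.A * (1.0 - upow * (1.0 + t / denom))
        if case.label == "ii":
            t_bar = _sensitivity_b_sign_change(p)
            profile = (
                f"positive up to t-bar = {t_bar:.6g} (> b/|a| = "
                f"{p.b / abs(p.a):.6g}), negative afterwards"
            )
        else:
            profile = "positive for all t > 0 in the domain"
            t_bar = None

    return SensitivityReport(
        parameter=parameter,  # type: ignore[arg-type]
        epsilon=epsilon,
        delta_curve=delta,
        sign_profile=profile,
        sign_change_time=t_bar,
    )
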