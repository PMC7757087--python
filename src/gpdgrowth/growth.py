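"""The generalized Gompertz growth curve driven by a generalized Pareto hazard.

The model is the solution of

    dN/dt = N(t) * A * (1 - log(N(t)/y) / (A*b)) ** (1+a),    N(0) = y,

equivalently ``N(t) = y * exp(A * integral_0^t Fbar(tau) dtau)`` where
``Fbar`` is the survival function of a generalized Pareto distribution (GPD)

    Fbar(t) = (b / (a*t + b)) ** (1/a + 1),

with rate scale ``A > 0``, shape ``a > -1`` (``a != 0``) and time scale
``b > 0``.  For ``a -> 0`` the GPD degenerates to the exponential
distribution and the curve to the classical Gompertz curve with
``alpha = A`` and ``beta = 1/b``; for ``a = b = 1/beta`` it reduces to the
modified Korf (DS) curve.  The shape parameter splits the qualitative
behaviour into four cases:

    (i)   a > 0: increasing on (0, inf), saturating at C = y*exp(A*b);
    (ii)  -1 < a < 0, 1/|a| odd integer: increasing through C at b/|a|,
          diverging afterwards;
    (iii) -1 < a < 0, 1/|a| even integer: maximum C at b/|a|, then
          decaying to zero;
    (iv)  -1 < a < 0, 1/|a| non-integer: defined on (0, b/|a|) only, with
          left limit C at the endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Union

import numpy as np
from scipy import integrate

from .errors import DomainError, NumericError, ParameterError

__all__ = [
    "GPDParams",
    "CaseLabel",
    "ReferenceModel",
    "GOMPERTZ_LIMIT_SHAPE",
    "gpd_survival",
    "gpd_curve",
    "gpd_rate",
    "classify_case",
    "carrying_capacity",
    "reference_curve",
    "curve_from_survival",
    "correction_factor",
]

#: below this |a| the (.)**(1/a) branch overflows and the exact Gompertz
#: limit (alpha=A, beta=1/b) is used instead
GOMPERTZ_LIMIT_SHAPE = 1e-8

#: relative tolerance of the "is 1/|a| an integer" test that separates
#: cases (ii)/(iii) from case (iv)
_INTEGER_RTOL = 1e-9


@dataclass(frozen=True)
class GPDParams:
    """Parameter quadruple of the GPD growth curve.

    Attributes
    ----------
    y : float
        Initial size ``N(0) > 0``.
    A : float
        Rate scale (time^-1), ``A > 0``.
    a : float
        GPD shape, ``a > -1`` and ``a != 0`` (values with ``|a|`` below
        :data:`GOMPERTZ_LIMIT_SHAPE` are evaluated on the Gompertz-limit
        branch).
    b : float
        GPD time scale, ``b > 0``.
    """

    y: float
    A: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("y", "A", "b"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.a) or self.a <= -1 or self.a == 0:
            raise ParameterError(f"a must satisfy a > -1, a != 0, got {self.a!r}")

    @property
    def carrying_capacity(self) -> float:
        """Finite saturation level ``C = y * exp(A*b)``."""
        return self.y * math.exp(self.A * self.b)

    @property
    def domain_end(self) -> float:
        """Right endpoint of the time domain: ``b/|a|`` when the curve is
        only defined up to there (case iv), otherwise ``inf``."""
        return classify_case(self).domain_end


@dataclass(frozen=True)
class CaseLabel:
    """Qualitative case of the curve and, where relevant, its domain end."""

    label: Literal["i", "ii", "iii", "iv"]
    domain_end: float  # math.inf for cases i-iii

    def __post_init__(self) -> None:
        if self.label == "iv" and not np.isfinite(self.domain_end):
            raise ParameterError("case iv requires a finite domain end")
        if self.label != "iv" and np.isfinite(self.domain_end):
            raise ParameterError("cases i-iii have an infinite domain")


@dataclass(frozen=True)
class ReferenceModel:
    """One of the classical comparison curves.

    ``kind`` selects the closed form; ``params`` is the kind's tuple:

    - ``gompertz``: (y, alpha, beta) -> y*exp{(alpha/beta)(1-exp(-beta t))}
    - ``logistic``: (y, r, C)        -> C / (1 + ((C-y)/y) exp(-r t))
    - ``korf``:     (alpha, beta, y) -> y*exp{(alpha/beta)(1-t^-beta)}, t>0
    - ``ds``:       (y, alpha, beta) -> y*exp{(alpha/beta)(1-(1+t)^-beta)}
    - ``malthus``:  (y, r)           -> y*exp(r t)
    """

    kind: Literal["gompertz", "logistic", "korf", "ds", "malthus"]
    params: tuple

    def __post_init__(self) -> None:
        n_expected = {"gompertz": 3, "logistic": 3, "korf": 3, "ds": 3, "malthus": 2}
        if self.kind not in n_expected:
            raise ParameterError(f"unknown reference model kind {self.kind!r}")
        if len(self.params) != n_expected[self.kind]:
            raise ParameterError(
                f"{self.kind} takes {n_expected[self.kind]} parameters, "
                f"got {len(self.params)}"
            )
        if any(p <= 0 for p in self.params):
            raise ParameterError("all reference-model parameters must be > 0")
        if self.kind == "logistic":
            y, _, C = self.params
            if C <= y:
                raise ParameterError("logistic requires C > y")


def _check_survival_shape(a: float, b: float) -> None:
    if not (np.isfinite(b) and b > 0):
        raise ParameterError(f"b must be finite and > 0, got {b!r}")
    if not np.isfinite(a) or a <= -1 or a == 0:
        raise ParameterError(f"a must satisfy a > -1, a != 0, got {a!r}")


def gpd_survival(t, a: float, b: float):
    """Survival function ``(b/(a t + b))^(1/a + 1)`` of the GPD.

    For ``a < 0`` the support ends at ``b/|a|``; beyond it the survival is 0.
    ``|a|`` below :data:`GOMPERTZ_LIMIT_SHAPE` uses the exponential limit
    ``exp(-t/b)``.  Accepts scalar or array ``t >= 0``.
    """
    _check_survival_shape(a, b)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    if abs(a) < GOMPERTZ_LIMIT_SHAPE:
        out = np.exp(-t / b)
    else:
        denom = a * t + b
        with np.errstate(divide="ignore", over="ignore"):
            u = np.where(denom > 0, b / np.where(denom > 0, denom, 1.0), np.inf)
            out = np.where(denom > 0, u ** (1.0 / a + 1.0), 0.0)
    return out if out.ndim else float(out)


def classify_case(p: GPDParams) -> CaseLabel:
    """Assign the qualitative case (i)-(iv) of the growth curve."""
    if p.a > 0 or abs(p.a) < GOMPERTZ_LIMIT_SHAPE:
        return CaseLabel("i", math.inf)
    recip = 1.0 / abs(p.a)
    nearest = round(recip)
    if nearest >= 1 and abs(recip - nearest) <= _INTEGER_RTOL * recip:
        label = "ii" if nearest % 2 == 1 else "iii"
        return CaseLabel(label, math.inf)
    return CaseLabel("iv", p.b / abs(p.a))


def _signed_power(u, exponent_int: int):
    """``u ** exponent_int`` for real u (possibly negative) and integer
    exponent, vectorized; ``u = +-inf`` with negative exponent gives 0."""
    with np.errstate(divide="ignore", over="ignore"):
        mag = np.abs(u) ** float(exponent_int)
    sign = np.where((u < 0) & (exponent_int % 2 == 1), -1.0, 1.0)
    return sign * mag


def _exponent_term(t: np.ndarray, p: GPDParams, case: CaseLabel) -> np.ndarray:
    """``(b/(a t + b)) ** (1/a)`` on the case's domain, with the signed
    integer-power continuation past b/|a| for cases (ii)/(iii)."""
    a, b = p.a, p.b
    denom = a * t + b
    if case.label == "i":
        return (b / denom) ** (1.0 / a)
    if case.label == "iv":
        return (b / denom) ** (1.0 / a)
    # cases ii/iii: 1/a = -m with integer m = 1/|a|
    m = round(1.0 / abs(a))
    with np.errstate(divide="ignore"):
        u = np.where(denom != 0, b / np.where(denom != 0, denom, 1.0), np.inf)
    return _signed_power(u, -m)


def _validate_times(t, p: GPDParams, case: CaseLabel) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    if case.label == "iv" and np.any(t >= case.domain_end):
        raise DomainError(
            f"curve undefined for t >= b/|a| = {case.domain_end:g} (case iv); "
            "the one-sided limit there equals the carrying capacity"
        )
    return t


def gpd_curve(t, p: GPDParams):
    """Evaluate ``N(t) = y * exp{A b [1 - (b/(a t + b))^(1/a)]}``.

    Scalar or array ``t``.  Case (iv) raises :class:`DomainError` for
    ``t >= b/|a|``; cases (ii)/(iii) evaluate everywhere, returning ``C``
    exactly at ``t = b/|a|`` by continuity.
    """
    case = classify_case(p)
    t = _validate_times(t, p, case)
    if abs(p.a) < GOMPERTZ_LIMIT_SHAPE:
        out = p.y * np.exp(p.A * p.b * (1.0 - np.exp(-t / p.b)))
    else:
        out = p.y * np.exp(p.A * p.b * (1.0 - _exponent_term(t, p, case)))
    return out if out.ndim else float(out)


def gpd_rate(t, p: GPDParams):
    """Per-capita growth rate ``xi(t) = (dN/dt)/N = A (b/(a t+b))^(1/a+1)``.

    On the GPD support this equals ``A * gpd_survival(t, a, b)``; for cases
    (ii)/(iii) past ``b/|a|`` it continues the derivative analytically
    (negative in case (iii) where the curve decays).
    """
    case = classify_case(p)
    t = _validate_times(t, p, case)
    if abs(p.a) < GOMPERTZ_LIMIT_SHAPE:
        out = p.A * np.exp(-t / p.b)
    elif case.label in ("i", "iv"):
        out = p.A * (p.b / (p.a * t + p.b)) ** (1.0 / p.a + 1.0)
    else:
        m = round(1.0 / abs(p.a))
        denom = p.a * t + p.b
        with np.errstate(divide="ignore"):
            u = np.where(denom != 0, p.b / np.where(denom != 0, denom, 1.0), np.inf)
        out = p.A * _signed_power(u, -(m - 1))
    return out if np.ndim(out) else float(out)


def carrying_capacity(p: GPDParams) -> float:
    """``C = y * exp(A*b)`` (Eq.-level identity; the curve's limit in case
    (i), its value at ``b/|a|`` in cases (ii)/(iii), its left endpoint
    limit in case (iv))."""
    return p.carrying_capacity


def reference_curve(t, m: ReferenceModel):
    """Evaluate one of the classical reference growth curves at ``t``."""
    t = np.asarray(t, dtype=float)
    if m.kind == "korf":
        if np.any(t <= 0):
            raise DomainError("the Korf curve is defined for t > 0 only")
    elif np.any(t < 0):
        raise DomainError("t must be >= 0")
    if m.kind == "gompertz":
        y, alpha, beta = m.params
        out = y * np.exp(alpha / beta * (1.0 - np.exp(-beta * t)))
    elif m.kind == "logistic":
        y, r, C = m.params
        out = C / (1.0 + (C - y) / y * np.exp(-r * t))
    elif m.kind == "korf":
        alpha, beta, y = m.params
        out = y * np.exp(alpha / beta * (1.0 - t ** (-beta)))
    elif m.kind == "ds":
        y, alpha, beta = m.params
        out = y * np.exp(alpha / beta * (1.0 - (1.0 + t) ** (-beta)))
    else:  # malthus
        y, r = m.params
        out = y * np.exp(r * t)
    return out if out.ndim else float(out)


def curve_from_survival(
    survival: Callable[[float], float], A: float, y: float, t: float
) -> float:
    """Growth curve ``y * exp{A * integral_0^t survival(tau) dtau}`` for an
    arbitrary survival function, via adaptive quadrature.

    This is the construction every curve in this module specialises: the
    hazard of the driving lifetime distribution shapes the deceleration of
    the growth.
    """
    if A <= 0 or y <= 0:
        raise ParameterError("A and y must be > 0")
    if t < 0:
        raise DomainError("t must be >= 0")
    if t == 0:
        return float(y)
    integral, abserr = integrate.quad(
        survival, 0.0, t, epsabs=1e-10, epsrel=1e-10, limit=200
    )
    if not np.isfinite(integral) or abserr > 1e-6 * max(1.0, abs(integral)):
        raise NumericError(
            f"survival quadrature did not converge (estimate {integral!r}, "
            f"error {abserr!r})"
        )
    return float(y * math.exp(A * integral))


def correction_factor(z, p: GPDParams):
    """Density-dependence factor ``f(z) = (1 - log(z/y)/(A b))^(1+a)``.

    Satisfies ``A * f(N(t)) = xi(t)``; ``f(y) = 1`` (exponential growth
    reference) and ``f(C) = 0``.  Requires ``0 < z <= C`` unless ``1+a`` is
    an integer.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise DomainError("z must be > 0")
    base = 1.0 - np.log(z / p.y) / (p.A * p.b)
    expo = 1.0 + p.a
    if np.any(base < 0) and abs(expo - round(expo)) > 1e-12:
        raise DomainError(
            "z exceeds the carrying capacity and (1+a) is not an integer"
        )
    if np.any(base < 0):
        out = _signed_power(base, round(expo))
    else:
        out = base ** expo
    return out if np.ndim(out) else float(out)


ModelParams = Union[GPDParams, ReferenceModel]
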