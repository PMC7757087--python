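"""Time-inhomogeneous linear birth-death process with GPD net growth rate.

The process ``X(t)`` on {0, 1, 2, ...} has transition rates
``i*lambda(t)`` (birth) and ``i*mu(t)`` (death); state 0 is absorbing.
Its conditional mean equals the GPD growth curve exactly when the net
per-capita rate is the curve's rate,

    lambda(t) - mu(t) = A (b/(a t + b))^(1/a + 1),      a > 0,

which this module enforces: a death-rate shape is chosen from the four
cases below and the birth rate is the net rate plus that death rate.

    (a) mu(t) = c                          constant mortality
    (b) mu(t) = c + d (t - t0) 1{t>=t0}    delayed linear worsening
    (c) mu(t) = c + d sin(2 pi t / Q)      seasonal mortality (c > |d|)
    (d) mu(t) = c (b/(a t + b))^(1/a+1)    mortality proportional to births

Transition probabilities, moments and the ultimate-extinction probability
are expressed through the two transforms

    psi(t) = exp{-int_0^t (lambda - mu)}  (closed form: exp{-Lambda(t)}),
    phi(t) = int_0^t lambda(tau) psi(tau) dtau.

Because ``psi' = -(lambda - mu) psi``, the net-rate part of phi integrates
exactly: ``phi(t) = 1 - psi(t) + int_0^t mu(tau) psi(tau) dtau``, and only
the mu-part needs quadrature.  In cases (a)-(c) that part diverges
linearly, making ultimate extinction certain; in case (d) it converges and
``phi(inf) = (1 + c/A)(1 - e^{-A b})``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
from scipy import integrate

from .errors import NumericError, ParameterError
from .growth import GPDParams

__all__ = [
    "BDSpec",
    "PsiPhi",
    "net_rate",
    "psi_phi",
    "bd_transition_probability",
    "bd_mean_variance",
    "extinction_probability",
    "extinction_probability_numeric",
]

_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class BDSpec:
    """Birth-death specification: GPD net rate plus a death-rate case."""

    gpd: GPDParams
    mu_case: Literal["a", "b", "c", "d"]
    c: float
    d: float = 0.0
    Q: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.gpd.a <= 0:
            raise ParameterError(
                "the birth-death construction requires shape a > 0 "
                "(saturating case (i))"
            )
        if self.mu_case not in ("a", "b", "c", "d"):
            raise ParameterError(f"unknown mu case {self.mu_case!r}")
        if self.c <= 0:
            raise ParameterError("c must be > 0")
        if self.mu_case == "b" and (self.d <= 0 or self.t0 <= 0):
            raise ParameterError("case (b) needs d > 0 and t0 > 0")
        if self.mu_case == "c":
            if self.Q <= 0:
                raise ParameterError("case (c) needs period Q > 0")
            if not abs(self.d) < self.c:
                raise ParameterError("case (c) needs c > |d| so mu stays positive")

    def mu(self, t):
        """Individual death rate at time t."""
        t = np.asarray(t, dtype=float)
        if self.mu_case == "a":
            out = np.full_like(t, self.c)
        elif self.mu_case == "b":
            out = self.c + self.d * np.where(t >= self.t0, t - self.t0, 0.0)
        elif self.mu_case == "c":
            out = self.c + self.d * np.sin(2.0 * math.pi * t / self.Q)
        else:
            out = self.c * np.asarray(_net_unit(t, self.gpd))
        out = np.asarray(out)
        return out if out.ndim else float(out)

    def lam(self, t):
        """Individual birth rate lambda(t) = net rate + mu(t)."""
        return net_rate(t, self) + self.mu(t)


def _net_unit(t, p: GPDParams):
    """``(b/(a t + b))^(1/a + 1)`` (the net rate for A = 1)."""
    t = np.asarray(t, dtype=float)
    out = (p.b / (p.a * t + p.b)) ** (1.0 / p.a + 1.0)
    return out if out.ndim else float(out)


def net_rate(t, spec: BDSpec):
    """Net per-capita rate ``lambda - mu = A (b/(a t+b))^(1/a+1)``,
    positive and decreasing to 0 with ``int_0^inf = A b``."""
    p = spec.gpd
    out = p.A * _net_unit(t, p)
    return out if np.ndim(out) else float(out)


def _psi(t, p: GPDParams):
    """``psi(t) = exp{-A b [1 - (b/(a t + b))^(1/a)]}``, limit e^{-A b}."""
    t = np.asarray(t, dtype=float)
    out = np.exp(-p.A * p.b * (1.0 - (p.b / (p.a * t + p.b)) ** (1.0 / p.a)))
    return out if out.ndim else float(out)


def _phi_mu_part(t: float, spec: BDSpec) -> float:
    """``int_0^t mu(tau) psi(tau) dtau`` by adaptive quadrature."""
    p = spec.gpd
    if t == 0.0:
        return 0.0

    def psi_f(tau: float) -> float:
        return _psi(tau, p)

    def smooth(tau: float) -> float:
        return spec.mu(tau) * psi_f(tau)

    if spec.mu_case == "c":
        # split the oscillatory part off and use quad's sin-weight rule
        const, err1 = integrate.quad(
            psi_f, 0.0, t, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400
        )
        osc, err2 = integrate.quad(
            psi_f, 0.0, t, weight="sin", wvar=2.0 * math.pi / spec.Q, limit=2000
        )
        val, err = spec.c * const + spec.d * osc, abs(err1) + abs(err2)
    elif spec.mu_case == "b":
        pieces = []
        err = 0.0
        for lo, hi in ((0.0, min(t, spec.t0)), (min(t, spec.t0), t)):
            if hi > lo:
                v, e = integrate.quad(
                    smooth, lo, hi, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400
                )
                pieces.append(v)
                err += abs(e)
        val = sum(pieces)
    else:
        val, err = integrate.quad(
            smooth, 0.0, t, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400
        )
    if not np.isfinite(val):
        raise NumericError(f"phi quadrature failed at t={t!r}")
    return float(val)


@dataclass(frozen=True)
class PsiPhi:
    """The (psi, phi) transform pair of one birth-death specification."""

    psi: Callable[[float], float]
    phi: Callable[[float], float]
    psi_inf: float
    phi_inf: float  # math.inf when the death-rate integral diverges


def phi_case_d_closed(t, spec: BDSpec):
    """Closed form ``phi_d(t) = (1 + c/A)(1 - psi(t))`` available in case
    (d), where mu is proportional to the net rate."""
    if spec.mu_case != "d":
        raise ParameterError("closed-form phi only exists for case (d)")
    return (1.0 + spec.c / spec.gpd.A) * (1.0 - _psi(t, spec.gpd))


def psi_phi(spec: BDSpec) -> PsiPhi:
    """Build the transform pair for a specification.

    ``psi`` is the closed form; ``phi`` combines the exact net-rate part
    ``1 - psi(t)`` with quadrature of the mu-part.
    """
    p = spec.gpd

    def psi_fun(t: float) -> float:
        return float(_psi(t, p))

    def phi_fun(t: float) -> float:
        if t < 0:
            raise ParameterError("t must be >= 0")
        return float(1.0 - _psi(t, p) + _phi_mu_part(float(t), spec))

    psi_inf = math.exp(-p.A * p.b)
    if spec.mu_case == "d":
        phi_inf = (1.0 + spec.c / p.A) * (1.0 - psi_inf)
    else:
        phi_inf = math.inf  # mu integral diverges in cases (a)-(c)
    return PsiPhi(psi=psi_fun, phi=phi_fun, psi_inf=psi_inf, phi_inf=phi_inf)


def _bd_transition_from_psi_phi(x: int, y: int, psi: float, phi: float) -> float:
    """Transition probability P_{y,x} expressed through scalar (psi, phi).

    ``P_{y,0} = (1 - 1/(psi+phi))^y`` and for x >= 1

    ``P_{y,x} = (phi/(psi+phi))^x  sum_{i=0}^{min(x,y)} C(y,i)
    C(y+x-i-1, y-1) (1/phi - 1)^i (1 - 1/(psi+phi))^{y-i}``.

    Terms can alternate in sign (phi > 1), so the sum is exact-combinatoric
    in floats rather than log-space.
    """
    if y < 1 or x < 0:
        raise ParameterError("need initial state y >= 1 and x >= 0")
    if psi <= 0 or phi < 0:
        raise ParameterError("psi must be > 0 and phi >= 0")
    s = psi + phi
    if x == 0:
        return float((1.0 - 1.0 / s) ** y)
    if phi == 0.0:
        # no births have been possible yet: at t=0, X = y surely
        return 1.0 if x == y else 0.0
    m = min(x, y)
    ratio = phi / s
    base0 = 1.0 - 1.0 / s
    alt = 1.0 / phi - 1.0
    total = 0.0
    for i in range(m + 1):
        total += (
            math.comb(y, i)
            * math.comb(y + x - i - 1, y - 1)
            * alt ** i
            * base0 ** (y - i)
        )
    return float(ratio ** x * total)


def bd_transition_probability(x: int, t: float, y: int, spec: BDSpec) -> float:
    """Probability that the population moves from ``y`` to ``x`` in time
    ``t``; ``x = 0`` is absorption (extinction before t)."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    if t == 0:
        return 1.0 if x == y else 0.0
    pp = psi_phi(spec)
    return _bd_transition_from_psi_phi(x, y, pp.psi(t), pp.phi(t))


def bd_distribution(
    t: float, y: int, spec: BDSpec, tail: float = 1e-12, max_states: int = 100000
) -> np.ndarray:
    """State distribution ``[P_{y,0}(t), P_{y,1}(t), ...]`` truncated
    adaptively: states are appended until the captured mass exceeds
    ``1 - tail``."""
    pp = psi_phi(spec)
    ps, ph = pp.psi(t), pp.phi(t)
    probs = [_bd_transition_from_psi_phi(0, y, ps, ph)]
    x = 1
    while sum(probs) < 1.0 - tail and x <= max_states:
        probs.append(_bd_transition_from_psi_phi(x, y, ps, ph))
        x += 1
    return np.asarray(probs)


def bd_mean_variance(t: float, y: int, spec: BDSpec) -> tuple[float, float]:
    """Conditional mean ``y/psi(t)`` (identical to the GPD growth curve
    with initial size y) and variance ``y (psi + 2 phi - 1)/psi^2``."""
    if y < 1:
        raise ParameterError("y must be >= 1")
    pp = psi_phi(spec)
    ps, ph = pp.psi(t), pp.phi(t)
    mean = y / ps
    var = y * (ps + 2.0 * ph - 1.0) / ps ** 2
    return float(mean), float(var)


def extinction_probability(y: int, spec: BDSpec) -> float:
    """Ultimate extinction probability ``(1 - 1/(psi_inf + phi_inf))^y``.

    Cases (a)-(c): the death-rate integral diverges, so ``phi_inf = inf``
    and extinction is certain.  Case (d):
    ``[ (c/A)(1-e^{-Ab}) / ((c/A)(1-e^{-Ab}) + 1) ]^y``.
    """
    if y < 1:
        raise ParameterError("y must be >= 1")
    pp = psi_phi(spec)
    if math.isinf(pp.phi_inf):
        return 1.0
    s = pp.psi_inf + pp.phi_inf
    return float((1.0 - 1.0 / s) ** y)


def extinction_probability_numeric(
    y: int,
    spec: BDSpec,
    times: tuple[float, ...] = (1e2, 1e3, 1e4),
) -> float:
    """Numeric evaluation of the ultimate-extinction limit.

    Evaluates ``P_{y,0}(t) = (1 - 1/(psi(t)+phi(t)))^y`` on the given time
    grid and extrapolates ``t -> inf`` by collocation in a power basis
    matched to the known tail of ``phi``:

    - cases (a)-(c): ``phi(t) = alpha t + O(sqrt(t))`` diverges, so
      ``pi(t) = pi_inf - c1/t + c2/t^{3/2} + ...`` -- basis
      ``{1, t^{-1}, t^{-3/2}}``;
    - case (d): ``phi`` converges and ``psi, phi`` approach their limits
      like ``t^{-1/2}`` (the GPD survival tail), so the basis is
      ``{1, t^{-1/2}, t^{-1}}``.

    Provides an independent check of :func:`extinction_probability`.
    """
    if len(times) < 3:
        raise ParameterError("need at least 3 grid times to extrapolate")
    pp = psi_phi(spec)
    ts = np.asarray(sorted(times), dtype=float)
    vals = np.array(
        [(1.0 - 1.0 / (pp.psi(t) + pp.phi(t))) ** y for t in ts]
    )
    if math.isinf(pp.phi_inf):
        exponents = (0.0, -1.0, -1.5)
    else:
        exponents = (0.0, -0.5, -1.0)
    design = np.column_stack([ts ** e for e in exponents])
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    return float(min(coef[0], 1.0))
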