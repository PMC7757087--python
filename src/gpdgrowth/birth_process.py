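"""Pure time-inhomogeneous linear birth process matching the GPD curve.

With death rate zero and per-capita birth rate
``lambda(t) = A (b/(a t + b))^(1/a + 1)`` (``a > 0``), the process ``X(t)``
started at ``X(0) = y`` has the negative-binomial transition law

    P_{y,x}(t) = C(x-1, y-1) e^{-y Lambda(t)} (1 - e^{-Lambda(t)})^{x-y},

driven by the cumulative individual intensity
``Lambda(t) = A b [1 - (b/(a t + b))^(1/a)]``, which saturates at ``A b``.
Saturation makes the total number of births finite: each inter-birth law is
defective, with probability ``exp{-(k+y)[A b - Lambda(tau)]}`` that no
further birth ever occurs.  The mean ``y e^{Lambda(t)}`` coincides with the
GPD growth curve; the Fano factor ``e^{Lambda(t)} - 1`` crosses 1 (Poisson
dispersion) at ``t* = Lambda^{-1}(log 2)`` whenever ``A > log(2)/b``.

The module also provides the first-passage-time density through constant
levels, the analytic survival through nonincreasing boundaries, an exact
event-based path simulator (inverse-Lambda sampling), and Monte Carlo
first-passage estimation through arbitrary moving boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy import integrate
from scipy.special import gammaln

from .errors import DomainError, ParameterError
from .growth import GPDParams

__all__ = [
    "BirthProcessSpec",
    "BirthPath",
    "Boundary",
    "FPTEstimate",
    "cumulative_intensity",
    "inverse_cumulative_intensity",
    "bp_transition_probability",
    "bp_moments",
    "BPMoments",
    "dispersion_transition_time",
    "fpt_density",
    "fpt_survival_nonincreasing",
    "simulate_path",
    "fpt_simulate",
]


@dataclass(frozen=True)
class BirthProcessSpec:
    """GPD parameters (shape ``a > 0``) plus an integer initial state."""

    gpd: GPDParams
    y: int = 1

    def __post_init__(self) -> None:
        if self.gpd.a <= 0:
            raise ParameterError("the pure birth process requires shape a > 0")
        if not (isinstance(self.y, (int, np.integer)) and self.y >= 1):
            raise ParameterError("initial state y must be an integer >= 1")

    @property
    def total_intensity(self) -> float:
        """``Lambda(inf) = A b``."""
        return self.gpd.A * self.gpd.b

    def lam(self, t):
        """Individual birth rate ``lambda(t)``."""
        p = self.gpd
        t = np.asarray(t, dtype=float)
        out = p.A * (p.b / (p.a * t + p.b)) ** (1.0 / p.a + 1.0)
        return out if out.ndim else float(out)


def cumulative_intensity(t, spec: BirthProcessSpec):
    """``Lambda(t) = A b [1 - (b/(a t + b))^(1/a)]``, saturating at A b."""
    p = spec.gpd
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    out = p.A * p.b * (1.0 - (p.b / (p.a * t + p.b)) ** (1.0 / p.a))
    return out if out.ndim else float(out)


def inverse_cumulative_intensity(s, spec: BirthProcessSpec):
    """``Lambda^{-1}(s) = (b/a) [ (1 - s/(A b))^{-a} - 1 ]`` for
    ``0 <= s < A b`` (the intensity never exceeds its saturation)."""
    p = spec.gpd
    s = np.asarray(s, dtype=float)
    Ab = spec.total_intensity
    if np.any(s < 0) or np.any(s >= Ab):
        raise DomainError(f"s must lie in [0, A*b) = [0, {Ab:g})")
    out = (p.b / p.a) * ((1.0 - s / Ab) ** (-p.a) - 1.0)
    return out if out.ndim else float(out)


def bp_transition_probability(x: int, t: float, spec: BirthProcessSpec) -> float:
    """Negative-binomial transition probability P_{y,x}(t); zero for
    ``x < y`` (no downward jumps).  Evaluated in log-space."""
    y = spec.y
    if x < y:
        return 0.0
    if t < 0:
        raise DomainError("t must be >= 0")
    lam_t = float(cumulative_intensity(t, spec))
    if lam_t == 0.0:
        return 1.0 if x == y else 0.0
    log_q = math.log1p(-math.exp(-lam_t))  # log(1 - e^-Lambda)
    log_p = (
        gammaln(x) - gammaln(y) - gammaln(x - y + 1)
        - y * lam_t + (x - y) * log_q
    )
    return float(math.exp(log_p))


@dataclass(frozen=True)
class BPMoments:
    mean: float
    variance: float
    fano: float
    cv: float


def bp_moments(t: float, spec: BirthProcessSpec) -> BPMoments:
    """Mean ``y e^Lambda``, variance ``y e^Lambda (e^Lambda - 1)``, Fano
    factor ``e^Lambda - 1`` and coefficient of variation
    ``y^{-1/2} sqrt(1 - e^{-Lambda})`` at time ``t``."""
    lam_t = float(cumulative_intensity(t, spec))
    e = math.exp(lam_t) if lam_t < 700.0 else math.inf
    y = spec.y
    return BPMoments(
        mean=y * e,
        variance=y * e * (e - 1.0) if math.isfinite(e) else math.inf,
        fano=e - 1.0,
        cv=math.sqrt((1.0 - math.exp(-lam_t)) / y),
    )


def dispersion_transition_time(spec: BirthProcessSpec) -> Optional[float]:
    """Time ``t*`` where the Fano factor crosses 1 (under- to
    overdispersed relative to Poisson), or ``None`` when ``A <= log(2)/b``
    and the process stays underdispersed forever."""
    p = spec.gpd
    if p.A * p.b <= math.log(2.0):
        return None
    return float(inverse_cumulative_intensity(math.log(2.0), spec))


def fpt_density(t, k: int, spec: BirthProcessSpec):
    """Defective first-passage density through the constant level ``k > y``:
    ``g_{y,k}(t) = (k-1) lambda(t) P_{y,k-1}(t)``.

    Its total mass is ``P(X(inf) >= k) < 1`` because the process may stall
    below ``k`` forever.
    """
    if k <= spec.y:
        raise ParameterError("the target level k must exceed the initial state y")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array(
        [(k - 1) * spec.lam(ti) * bp_transition_probability(k - 1, ti, spec)
         for ti in t_arr]
    )
    return out if np.ndim(t) else float(out[0])


def fpt_mass(k: int, spec: BirthProcessSpec) -> float:
    """Total mass of the defective FPT density: the limiting tail
    probability ``P(X(inf) >= k)`` of the saturated negative binomial."""
    if k <= spec.y:
        raise ParameterError("k must exceed y")
    Ab = spec.total_intensity
    q = -math.expm1(-Ab)  # 1 - e^{-Ab}
    # P(X_inf >= k) = sum_{x>=k} C(x-1,y-1) e^{-yAb} q^{x-y}
    total = 0.0
    x = k
    log_e = -spec.y * Ab
    while True:
        log_term = (
            gammaln(x) - gammaln(spec.y) - gammaln(x - spec.y + 1)
            + log_e + (x - spec.y) * math.log(q)
        )
        term = math.exp(log_term)
        total += term
        if term < 1e-16 * max(total, 1e-300) and x > k + 10:
            break
        x += 1
        if x > k + 100000:
            break
    return float(min(total, 1.0))


def fpt_survival_nonincreasing(
    t: float, boundary: "Boundary", spec: BirthProcessSpec
) -> float:
    """``P(T > t)`` through a *nonincreasing* boundary ``beta`` with
    ``beta(0) > y``: the sum of ``P_{y,n}(t)`` over states strictly below
    the boundary (integer boundary values count as reached, so the sum runs
    to ``beta(t) - 1`` when ``beta(t)`` is an integer)."""
    if not boundary.nonincreasing:
        raise ParameterError(
            "the analytic survival needs a nonincreasing boundary; "
            "use fpt_simulate for increasing or oscillating boundaries"
        )
    if boundary(0.0) <= spec.y:
        raise ParameterError("boundary must start above the initial state")
    bt = float(boundary(t))
    top = math.floor(bt)
    if top == bt:  # left-limit floor: integer boundary uses beta - 1
        top -= 1
    if top < spec.y:
        return 0.0
    return float(
        sum(bp_transition_probability(n, t, spec) for n in range(spec.y, top + 1))
    )


@dataclass(frozen=True)
class BirthPath:
    """One simulated trajectory: state after k births is ``initial + k``."""

    initial: int
    birth_times: np.ndarray
    terminated: bool
    seed: object = None

    def state_at(self, t: float) -> int:
        return self.initial + int(np.searchsorted(self.birth_times, t, side="right"))


@dataclass(frozen=True)
class Boundary:
    """Continuous moving boundary ``beta(t)`` with ``beta(0)`` above the
    initial state.

    Forms: ``constant`` (level ``k``), ``log`` (``log(t+1) + beta0``),
    ``sinusoid`` (``d sin(pi t / Q) + beta0``) or ``custom`` (any callable).
    """

    form: Literal["constant", "log", "sinusoid", "custom"]
    level: float = 0.0
    beta0: float = 0.0
    d: float = 0.0
    Q: float = 1.0
    func: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.form not in ("constant", "log", "sinusoid", "custom"):
            raise ParameterError(f"unknown boundary form {self.form!r}")
        if self.form == "custom" and self.func is None:
            raise ParameterError("custom boundary needs func")
        if self.form == "sinusoid" and self.Q <= 0:
            raise ParameterError("sinusoid boundary needs Q > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "constant":
            out = np.full_like(t, self.level)
        elif self.form == "log":
            out = np.log(t + 1.0) + self.beta0
        elif self.form == "sinusoid":
            out = self.d * np.sin(math.pi * t / self.Q) + self.beta0
        else:
            out = np.asarray(self.func(t), dtype=float)
        return out if out.ndim else float(out)

    @property
    def nonincreasing(self) -> bool:
        if self.form == "constant":
            return True
        if self.form == "log":
            return False
        if self.form == "sinusoid":
            return self.d == 0.0
        tt = np.linspace(0.0, 1e3, 20001)
        return bool(np.all(np.diff(self(tt)) <= 1e-12))


def _path_rng(seed: int, index: int) -> np.random.Generator:
    """Independent stream for path ``index`` derived from the master seed,
    so results do not depend on n_paths or evaluation order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_path(
    spec: BirthProcessSpec,
    seed: Optional[int] = None,
    t_max: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> BirthPath:
    """Exact event-based simulation of one trajectory.

    Given the current state ``k + y`` at time ``tau``, the next birth never
    occurs with probability ``l = exp{-(k+y)[A b - Lambda(tau)]}``;
    otherwise it is sampled by inverting the cumulative intensity:
    ``T = Lambda^{-1}(Lambda(tau) - log(U)/(k+y))`` for ``U ~ U(l, 1)``.
    """
    if rng is None:
        if seed is None:
            raise ParameterError("provide seed or rng for reproducibility")
        rng = np.random.default_rng(seed)
    Ab = spec.total_intensity
    times: list[float] = []
    tau = 0.0
    lam_tau = 0.0
    k = 0
    terminated = False
    while True:
        ell = math.exp(-(k + spec.y) * (Ab - lam_tau))
        U = rng.uniform()
        if U <= ell:
            terminated = True
            break
        lam_next = lam_tau - math.log(U) / (k + spec.y)
        t_next = float(inverse_cumulative_intensity(lam_next, spec))
        if t_max is not None and t_next > t_max:
            break
        times.append(t_next)
        tau, lam_tau, k = t_next, lam_next, k + 1
    return BirthPath(
        initial=spec.y,
        birth_times=np.asarray(times, dtype=float),
        terminated=terminated,
        seed=seed,
    )


@dataclass(frozen=True)
class FPTEstimate:
    """Monte Carlo first-passage estimate through a moving boundary."""

    bin_edges: np.ndarray
    counts: np.ndarray
    crossing_ratio: float
    n_paths: int
    seed: int
    convention: str
    passage_times: np.ndarray = field(repr=False, default=None)

    @property
    def crossing_se(self) -> float:
        """Binomial standard error of the crossing ratio."""
        p = self.crossing_ratio
        return math.sqrt(p * (1.0 - p) / self.n_paths)


def _first_crossing(
    path: BirthPath,
    boundary: Boundary,
    grid: np.ndarray,
    beta_grid: np.ndarray,
    convention: str,
) -> Optional[float]:
    """First-passage time of one path, or None.

    ``attain``: first t with ``X(t) >= beta(t)`` -- a birth landing at or
    above the boundary, or the boundary dipping to the current state.
    ``equality``: first t with ``X(t) = beta(t)`` -- the boundary passing
    through the path's current (integer) level between jumps; a unit jump
    from below the boundary to strictly above it does NOT count.
    Between-jump events are detected on the supplied grid.
    """
    bt = path.birth_times
    states = path.initial + np.searchsorted(bt, grid, side="right")
    if convention == "attain":
        # exact check at birth instants
        if bt.size:
            beta_at_births = boundary(bt)
            new_states = path.initial + np.arange(1, bt.size + 1)
            hits = new_states >= beta_at_births
            t_birth = bt[hits][0] if np.any(hits) else math.inf
        else:
            t_birth = math.inf
        # boundary dipping to/below the current state between births
        dip = states >= beta_grid
        t_dip = grid[np.argmax(dip)] if bool(dip.any()) else math.inf
        t_cross = min(t_birth, t_dip)
        return None if math.isinf(t_cross) else float(t_cross)
    # equality: sign change of beta - X within a constant-state stretch
    diff = beta_grid - states
    same_state = states[1:] == states[:-1]
    sign_change = (np.sign(diff[1:]) != np.sign(diff[:-1])) & same_state
    if not bool(sign_change.any()):
        return None
    idx = int(np.argmax(sign_change))
    return float(grid[idx + 1])


def fpt_simulate(
    boundary: Boundary,
    spec: BirthProcessSpec,
    n_paths: int,
    seed: int,
    t_max: float = 50.0,
    convention: Literal["attain", "equality"] = "attain",
    grid_step: float = 0.01,
) -> FPTEstimate:
    """Estimate the first-passage-time law through a moving boundary.

    Simulates ``n_paths`` trajectories (one RNG stream per path index) up
    to ``t_max`` and records the passage time of each path under the chosen
    crossing convention; see :func:`_first_crossing`.  Returns a
    Freedman-Diaconis histogram of the finite passage times and the
    fraction of paths that reached the boundary.
    """
    if n_paths < 1:
        raise ParameterError("n_paths must be >= 1")
    if convention not in ("attain", "equality"):
        raise ParameterError(f"unknown crossing convention {convention!r}")
    grid = np.arange(0.0, t_max + grid_step, grid_step)
    beta_grid = np.asarray(boundary(grid), dtype=float)
    passages: list[float] = []
    for i in range(n_paths):
        path = simulate_path(spec, rng=_path_rng(seed, i), t_max=t_max)
        t_cross = _first_crossing(path, boundary, grid, beta_grid, convention)
        if t_cross is not None:
            passages.append(t_cross)
    passages_arr = np.asarray(passages, dtype=float)
    ratio = len(passages) / n_paths
    if passages_arr.size >= 2 and np.ptp(passages_arr) > 0:
        edges = np.histogram_bin_edges(passages_arr, bins="fd")
        counts, edges = np.histogram(passages_arr, bins=edges)
    else:
        edges = np.array([0.0, t_max])
        counts = np.array([passages_arr.size])
    return FPTEstimate(
        bin_edges=edges,
        counts=counts,
        crossing_ratio=ratio,
        n_paths=n_paths,
        seed=seed,
        convention=convention,
        passage_times=passages_arr,
    )


def fpt_mean_conditional(
    k: int, spec: BirthProcessSpec, t_upper: float = 1e4
) -> float:
    """Mean passage time through the constant level ``k``, conditional on
    the (defective) passage happening: ``int t g dt / int g dt``."""
    num, _ = integrate.quad(
        lambda t: t * fpt_density(t, k, spec), 0.0, t_upper, limit=400
    )
    den = fpt_mass(k, spec)
    return float(num / den)
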