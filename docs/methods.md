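# Methods

## The growth model

`gpdgrowth` implements the growth curve

    N(t) = y · exp{ A b [ 1 − (b/(a t + b))^(1/a) ] },        N(0) = y,

the solution of the density-dependent equation
`dN/dt = N · A · (1 − log(N/y)/(A b))^(1+a)`.  The construction behind it is
hazard-driven growth: for any nonnegative random lifetime X with survival
function F̄, the curve `N(t) = y exp{A ∫₀ᵗ F̄}` has per-capita growth rate
`ξ(t) = A F̄(t)`, so the shape of the deceleration is the shape of a survival
function.  Here X is generalized Pareto (GPD),
`F̄(t) = (b/(a t + b))^(1/a+1)`, which nests the three classical regimes:
Pareto tail for `a > 0`, bounded support (power distribution) for
`−1 < a < 0`, and the exponential limit `a → 0`, under which the curve
collapses to the Gompertz model with `α = A`, `β = 1/b`.  Setting
`a = b = 1/β` gives the modified-Korf (DS) curve.

### Parameters

| name | meaning                  | constraint            | units   |
|------|--------------------------|-----------------------|---------|
| `y`  | initial size             | `> 0`                 | size    |
| `A`  | initial per-capita rate  | `> 0`                 | 1/time  |
| `a`  | GPD shape                | `> −1`, `≠ 0`         | —       |
| `b`  | GPD time scale           | `> 0`                 | time    |

Time units are abstract (days, weeks, …) and taken from the data.  The
derived quantity `C = y·e^{Ab}` is the carrying value.

The sign and arithmetic of `a` split the behaviour into four cases:
(i) `a > 0` — monotone growth saturating at C; with `−1 < a < 0`, the
exponent branch changes at `t = b/|a|` and the curve (ii) passes through C
and diverges when `1/|a|` is an odd integer, (iii) peaks at C and decays to
zero when it is even, (iv) exists only on `(0, b/|a|)` otherwise, with left
limit C.  The integer test uses a relative tolerance of 1e-9; values of
`|a|` below 1e-8 are dispatched to the Gompertz closed form to avoid
overflow in `(·)^{1/a}`.  Cases (ii)/(iii) are evaluated past `b/|a|` with
exact signed integer powers, and the value at the breakpoint itself is C by
continuity.  For case (iv) the strict evaluator refuses `t ≥ b/|a|`; the
limit is exposed through the carrying value, not by extending the domain.

### Analytic features

When `A b > a + 1` the curve is sigmoidal with inflection at
`t_I = (b/a)[(Ab/(a+1))^a − 1]`, inflection size `C e^{−(a+1)}`, maximum
specific growth rate `μ = A y ((a+1)/(Ab))^{1+a} e^{Ab−(a+1)}` and lag time
`λ = (b/a)[(Ab/(a+1))^a/(a+1) − 1]` (the t-intercept of the tangent at the
inflection; negative λ means the curve takes off without a lag phase, which
happens whenever `A b ≤ (a+1)^{1/a+1}`).  Case-(ii) curves additionally
change concavity at `b/|a|`; the package reports that boundary inflection
separately (`boundary_inflection_time`) because it arises from the exponent
branch change, not from a root of the second derivative's bracket.

Threshold-crossing times invert the curve in closed form for an absolute
level, a fraction of C, or a fraction of the inflection size.  They are
covered by round-trip property tests (`N(θ^S) = S`).  Note one monotonicity
that is easy to get backwards: at a fixed fraction p, `θ_C(p)` *increases*
with A, because the target `p·C = p·y·e^{Ab}` inflates faster than the
curve accelerates.

First-order parameter sensitivities implement the Taylor expansions of the
curve in each parameter.  Signs: raising `y` or `A` raises the curve
everywhere, raising `a` lowers it everywhere, and raising `b` raises it
except in case (ii), where the effect flips sign at some `t̄ > b/|a|` that
the package locates by bracketing and Brent's method (tolerance 1e-8); only
existence of `t̄`, not its value, is available analytically.

## Fitting and the ISRP metric

Three models are fitted by unweighted nonlinear least squares: the GPD
curve, Gompertz `y exp{(α/β)(1−e^{−βt})}` and logistic
`C/(1+((C−y)/y)e^{−rt})`.  The optimiser is multi-start: `starts`
Latin-hypercube points (seeded, hence reproducible) drawn from data-driven
boxes — `y ∈ (0, 2·min value]`, rate parameters in `(0, 20]`, `b ∈ (0, 50]`,
logistic `C ∈ (max value, 100·max value]` — each refined by SciPy's bounded
trust-region-reflective `least_squares` with tight tolerances; the best
local minimum wins.  Inside the optimiser the GPD curve is evaluated with
`a t + b` clamped at a tiny positive value, which extends the curve
continuously by its limit C past a case-(iv) endpoint: optima can and do sit
exactly on the boundary `b/|a| = t_max` (the bundled software-failure data
produce one), and the optimiser must be able to cross it smoothly.  The
strict evaluator used by the public `ssr` keeps the hard domain error.

The ISRP (interval-specific rate parameter) re-estimates the model's
constant rate parameter (A, α or r) from each pair of consecutive
*observed* values, holding the other parameters at their fitted values.
Each estimator is algebraically exact on data generated by its model — for
the logistic model this dictates the interval statistic
`(1/Δt)·log[(C/n_i − 1)/(C/n_{i+1} − 1)]`; the additive constant printed in
some accounts of the logistic ISRP is not exact and was not used.  The `d₂`
statistic is the raw (unnormalised) Euclidean norm of the ISRP series minus
the constant, over the n−1 intervals.  Numerical caveat: near saturation
the increments that the estimators invert approach float cancellation, so
exactness is asserted in the informative regime only; a fitted GPD curve
that saturates before the last observation uses the limit value of its
power term (`w = 0`) for the saturated intervals.

One-step-ahead prediction refits the chosen model on the first `i−1`
observations and evaluates it at `t_i`, for each of the last `horizon`
indices — the standard expanding-window forecast exercise for cumulative
epidemic counts.

## Stochastic counterparts

### Linear birth–death process

`X(t)` has birth rate `i·λ(t)` and death rate `i·μ(t)` in state i, with 0
absorbing.  The conditional mean equals the GPD curve exactly when
`λ(t) − μ(t) = A(b/(at+b))^{1/a+1}` (enforced with `a > 0`, the saturating
case).  Death-rate shapes: (a) constant c; (b) constant then linearly
increasing after a delay t₀; (c) sinusoidal `c + d sin(2πt/Q)` with
`c > |d|`; (d) proportional to the net rate, `μ = (c/A)·(λ−μ)`.

Everything is expressed through `ψ(t) = exp{−∫(λ−μ)}` (closed form
`e^{−Λ(t)}`) and `φ(t) = ∫λψ`.  Because `ψ′ = −(λ−μ)ψ`, the net-rate part
of φ integrates exactly to `1 − ψ(t)`, so only `∫μψ` needs quadrature
(adaptive, tolerance 1e-10; the sinusoidal case uses the oscillatory
`weight="sin"` rule, which stays accurate over thousands of periods).  Case
(d) admits the closed form `φ_d = (1 + c/A)(1 − ψ)`, used as a cross-check
against the quadrature to 1e-8.  Published accounts of case (d) sometimes
carry a `c/a` factor in φ_d; the extinction probability they print alongside
uses `c/A`, and the quadrature oracle confirms `c/A` — the package uses it.
The incomplete-Gamma closed forms for cases (a)/(b) involve `Γ(−a, ·)` at
negative arguments, which is not real-valued for general `a`, so quadrature
is the primary path throughout.

Transition probabilities follow the classical (ψ, φ) formulas; the terms of
the finite sum alternate in sign once `φ > 1`, so they are evaluated with
exact integer binomial coefficients in double precision rather than in
log-space (states of interest are small; distribution sums extend the state
range adaptively until the captured mass exceeds `1 − 10⁻¹²`).  They are
validated against numerical integration of the truncated Kolmogorov forward
equations (200 states, LSODA) for all four death-rate cases.

Ultimate extinction: `π = (1 − 1/(ψ̃+φ̃))^y`.  For cases (a)–(c) the death
integral diverges, so `φ̃ = ∞` and extinction is certain (`π = 1` exactly).
Case (d) gives `π = [q/(q+1)]^y` with `q = (c/A)(1−e^{−Ab})`.  A numeric
cross-check evaluates `P_{y,0}(t)` at `t = 10², 10³, 10⁴` and extrapolates
`t → ∞` by collocation in a power basis matched to the tail of φ: for a
linearly growing death integral `φ = αt + O(√t)` the absorption probability
approaches its limit like `1/t` with a `t^{−3/2}` correction (basis
`{1, t⁻¹, t^{−3/2}}`); in case (d) ψ and φ converge like `t^{−1/2}` (the GPD
survival tail), so the basis is `{1, t^{−1/2}, t⁻¹}`.  The extrapolation
reaches ~2·10⁻⁴ of the exact limit in the divergent cases and ~10⁻⁶ in case
(d); direct evaluation at `t = 10⁴` alone is still ~3·10⁻³ away, which is
why the extrapolation exists.

### Pure birth process and first passage

With `μ ≡ 0` the process has the negative-binomial law
`P_{y,x}(t) = C(x−1, y−1) e^{−yΛ}(1−e^{−Λ})^{x−y}` driven by
`Λ(t) = Ab[1−(b/(at+b))^{1/a}]`, which saturates at `Ab`: the total number
of births is finite almost surely, inter-birth laws are defective, and the
mean `y·e^{Λ(t)}` equals the growth curve.  The Fano factor `e^Λ − 1`
crosses 1 at `t* = Λ⁻¹(log 2)` when `A > log(2)/b`; the coefficient of
variation `y^{−1/2}(1−e^{−Λ})^{1/2}` increases in t, A and b but *decreases*
in the shape a at fixed t, since `(1+at/b)^{−1/a} → 1` as `a` grows and the
accumulated intensity shrinks (statements to the contrary in the literature
do not survive the computation; the tests pin the verified direction).

Simulation is exact and event-based: from state `k+y` at time τ, the next
birth never occurs with probability `ℓ = e^{−(k+y)(Ab−Λ(τ))}`; otherwise
`U ~ Uniform(0,1)` maps to the birth time `Λ⁻¹(Λ(τ) − log U/(k+y))` by
inverse transform.  Each path consumes its own RNG stream
(`SeedSequence([master_seed, path_index])`), so results are independent of
`n_paths` and of evaluation order.  The simulator is validated against the
negative-binomial marginals by chi-square goodness of fit and against the
analytic first-passage density through constant levels,
`g_{y,k}(t) = (k−1)λ(t)P_{y,k−1}(t)` (defective: its mass is
`P(X(∞) ≥ k)`).  For nonincreasing boundaries the survival
`P(T > t) = Σ_{n<β(t)} P_{y,n}(t)` is available analytically, with the
left-limit floor convention (an integer boundary value counts as reached).

Moving-boundary first passage is Monte Carlo.  Two crossing conventions are
implemented because `T = inf{t : X(t) = β(t)}` is genuinely ambiguous for a
unit-jump process against a continuous boundary:

- `attain` (default): the path reaches β at a birth landing at or above the
  boundary, or when the boundary dips to the current state between births;
- `equality`: only an exact meeting counts — the boundary passing through
  the path's current integer level while the path holds it (a jump from
  strictly below to strictly above the boundary is a miss).

Between-birth events are detected on a uniform time grid (default step
0.01, convergence-checked: refining to 0.0025 moves the crossing ratios by
well under one Monte Carlo standard error).  The default horizon for the
shipped boundary studies is `t_max = 50`, by which the cumulative intensity
of the reference parameter set (A=1, a=0.5, b=3) has reached ~99% of its
saturation; under the equality convention later catches are still possible
(a slowly rising boundary eventually sweeps every frozen path), so the
reported crossing ratios are horizon-dependent by nature and the horizon is
part of the experiment definition.

## Synthetic data

`synthetic_growth_data` emulates cumulative surveillance counts: model
curve plus independent homoscedastic Gaussian noise on the size scale,
clipped at zero, seeded.  This matches the unweighted least-squares
criterion used in fitting.  It does not emulate reporting artefacts of real
surveillance series — weekday effects, retroactive corrections, dependence
between increments, or the fact that cumulative counts are nondecreasing
while noisy curve values need not be.  Passing recovery tests therefore
demonstrate optimiser correctness under the assumed noise model, not
robustness to real-world misreporting.  Default experiment sizes used by
the tests: 40 observations, noise 0.5% of C, 64 multi-start points.

## Numerical choices

- Quadrature tolerances 1e-10 (φ, survival integrals); feature root finding
  1e-8; integer test for `1/|a|` 1e-9 relative; Gompertz-limit dispatch at
  `|a| < 1e-8`.
- `bp_moments` returns infinite mean/variance once `Λ > 700` (exp overflow)
  instead of raising; the cv remains finite and exact.
- Multi-start boxes are deliberately generous rather than adaptive; with 64
  starts the Latin hypercube covers the 3–4 dimensional boxes densely
  enough that the fits in the test-suite reproduce the global optimum
  reproducibly across seeds.
- Histogram binning of passage times is Freedman–Diaconis.

## Known limitations

- The ISRP-based *estimation* procedure (choosing parameters to optimise
  the ISRP metric itself) is not implemented; parameters are estimated by
  least squares and the ISRP/d₂ is evaluated at those estimates.  The d₂
  normalisation in published tables is not fully specified, so d₂ values
  are comparable within this package but not guaranteed to match printed
  ones.
- Analytic first-passage through *increasing* boundaries is out of scope
  (simulation only), and the conditional mean passage time through a level
  uses quadrature to a finite upper limit.
- The birth–death and birth-process constructions require `a > 0`; the
  bounded-support cases of the deterministic curve have no stochastic
  counterpart here.
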