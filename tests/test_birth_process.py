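"""Pure birth process: intensity, law, dispersion, FPT, simulator."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from gpdgrowth import (
    BirthProcessSpec,
    Boundary,
    DomainError,
    GPDParams,
    ParameterError,
    bp_moments,
    bp_transition_probability,
    cumulative_intensity,
    dispersion_transition_time,
    fpt_density,
    fpt_simulate,
    fpt_survival_nonincreasing,
    inverse_cumulative_intensity,
    simulate_path,
)
from gpdgrowth.birth_death import _bd_transition_from_psi_phi
from gpdgrowth.birth_process import _path_rng, fpt_mass

SPEC_HALF = BirthProcessSpec(GPDParams(1.0, 1.0, 0.5, 3.0), y=1)  # A b = 3
SPEC_UNIT = BirthProcessSpec(GPDParams(1.0, 1.0, 1.0, 3.0), y=1)


class _ScriptedRng:
    """Deterministic uniform stream for exercising the sampling algebra."""

    def __init__(self, values):
        self._values = list(values)

    def uniform(self):
        return self._values.pop(0)


class TestIntensity:
    def test_limits(self):
        assert cumulative_intensity(0.0, SPEC_HALF) == 0.0
        assert cumulative_intensity(1e12, SPEC_HALF) == pytest.approx(3.0, rel=1e-5)

    def test_inverse_value(self):
        exact = 6.0 * ((1.0 - math.log(2.0) / 3.0) ** -0.5 - 1.0)
        got = inverse_cumulative_intensity(math.log(2.0), SPEC_HALF)
        assert got == pytest.approx(exact, rel=1e-12)
        assert got == pytest.approx(0.8423, abs=1e-4)

    def test_round_trip(self):
        s = cumulative_intensity(2.5, SPEC_HALF)
        assert inverse_cumulative_intensity(s, SPEC_HALF) == pytest.approx(
            2.5, abs=1e-10
        )

    def test_inverse_rejects_saturated_values(self):
        with pytest.raises(DomainError):
            inverse_cumulative_intensity(3.0, SPEC_HALF)


class TestTransitionLaw:
    def test_diagonal(self):
        for t in (0.5, 1.0, 3.0):
            lam_t = cumulative_intensity(t, SPEC_UNIT)
            assert bp_transition_probability(1, t, SPEC_UNIT) == pytest.approx(
                math.exp(-lam_t), rel=1e-12
            )

    def test_below_initial_state_is_zero(self):
        spec = BirthProcessSpec(GPDParams(2.0, 1.0, 1.0, 3.0), y=2)
        assert bp_transition_probability(1, 1.0, spec) == 0.0

    def test_normalisation(self):
        spec = BirthProcessSpec(GPDParams(2.0, 1.0, 1.0, 3.0), y=2)
        total = sum(bp_transition_probability(x, 1.0, spec) for x in range(2, 500))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_birth_death_at_zero_death_rate(self):
        """Cross-module oracle: psi + phi = 1 collapses the birth-death law
        to the pure-birth law."""
        for t in (0.3, 1.0, 2.5):
            psi = math.exp(-cumulative_intensity(t, SPEC_UNIT))
            for x in range(1, 15):
                bd = _bd_transition_from_psi_phi(x, 1, psi, 1.0 - psi)
                bp = bp_transition_probability(x, t, SPEC_UNIT)
                assert bd == pytest.approx(bp, rel=1e-10)


class TestMoments:
    def test_limits(self):
        mo = bp_moments(1e12, SPEC_UNIT)
        assert mo.mean == pytest.approx(math.exp(3.0), rel=1e-5)
        assert mo.variance == pytest.approx(math.exp(3) * (math.exp(3) - 1), rel=1e-4)

    def test_cv_limits_in_A(self):
        small = BirthProcessSpec(GPDParams(1.0, 1e-6, 1.0, 3.0), y=1)
        large = BirthProcessSpec(GPDParams(1.0, 1e4, 1.0, 3.0), y=4)
        assert bp_moments(5.0, small).cv < 2e-3
        assert bp_moments(5.0, large).cv == pytest.approx(4 ** -0.5, rel=1e-6)

    def test_cv_monotone_in_time_and_parameters(self):
        tt = np.linspace(0.1, 20, 40)
        cvs = [bp_moments(t, SPEC_UNIT).cv for t in tt]
        assert np.all(np.diff(cvs) > 0)
        # increasing in A and b; decreasing in the shape a at fixed t,
        # because (1 + a t/b)^(-1/a) rises toward 1 as a grows, shrinking
        # the accumulated intensity Lambda(t)
        for field, direction in (("A", +1), ("a", -1), ("b", +1)):
            vals = []
            for scale in (0.5, 1.0, 2.0):
                kw = {"y": 1.0, "A": 1.0, "a": 1.0, "b": 3.0}
                kw[field] = kw[field] * scale
                spec = BirthProcessSpec(GPDParams(**kw), y=1)
                vals.append(bp_moments(2.0, spec).cv)
            assert np.all(direction * np.diff(vals) > 0), field

    def test_fano_nondecreasing_and_crossing_at_t_star(self):
        t_star = dispersion_transition_time(SPEC_HALF)
        assert t_star == pytest.approx(0.8423, abs=1e-4)
        assert bp_moments(t_star, SPEC_HALF).fano == pytest.approx(1.0, abs=1e-10)
        tt = np.linspace(0, 30, 100)
        fanos = [bp_moments(t, SPEC_HALF).fano for t in tt]
        assert np.all(np.diff(fanos) > 0)
        assert bp_moments(t_star * 0.9, SPEC_HALF).fano < 1
        assert bp_moments(t_star * 1.1, SPEC_HALF).fano > 1

    def test_dispersion_time_absent_when_A_small(self):
        spec = BirthProcessSpec(GPDParams(1.0, 0.2, 1.0, 3.0), y=1)  # A b < log 2
        assert dispersion_transition_time(spec) is None


class TestFPTDensity:
    def test_short_time_limits(self):
        spec = BirthProcessSpec(GPDParams(1.0, 2.0, 2.0, 2.0), y=1)
        assert fpt_density(1e-12, 2, spec) == pytest.approx(2.0, rel=1e-6)
        assert fpt_density(1e-12, 3, spec) == pytest.approx(0.0, abs=1e-9)

    def test_total_mass_is_limiting_tail(self):
        """integral of g_{1,3} = P(X_inf >= 3) = (1 - e^{-A b})^2."""
        # integrate in s = Lambda(t): ds = lambda(t) dt maps [0,inf) to [0, A b)
        Ab = SPEC_UNIT.total_intensity

        def integrand(s):
            t = inverse_cumulative_intensity(s, SPEC_UNIT)
            return 2.0 * bp_transition_probability(2, t, SPEC_UNIT)

        total, _ = quad(integrand, 0.0, Ab, epsabs=1e-12, epsrel=1e-12, limit=400)
        closed = (1.0 - math.exp(-Ab)) ** 2
        assert total == pytest.approx(closed, rel=1e-8)
        assert fpt_mass(3, SPEC_UNIT) == pytest.approx(closed, rel=1e-10)

    def test_rejects_level_at_or_below_start(self):
        with pytest.raises(ParameterError):
            fpt_density(1.0, 1, SPEC_UNIT)


class TestFPTSurvivalNonincreasing:
    def test_starts_at_one(self):
        bnd = Boundary("constant", level=4.0)
        assert fpt_survival_nonincreasing(0.0, bnd, SPEC_UNIT) == pytest.approx(1.0)

    def test_constant_boundary_matches_density(self):
        bnd = Boundary("constant", level=4.0)
        t = 2.0
        g_mass, _ = quad(lambda u: fpt_density(u, 4, SPEC_UNIT), 0.0, t,
                         epsabs=1e-12, epsrel=1e-12, limit=400)
        surv = fpt_survival_nonincreasing(t, bnd, SPEC_UNIT)
        assert surv == pytest.approx(1.0 - g_mass, abs=1e-8)

    def test_boundary_hugging_next_level(self):
        bnd = Boundary("constant", level=1.9999999)
        t = 1.5
        expected = math.exp(-cumulative_intensity(t, SPEC_UNIT))
        assert fpt_survival_nonincreasing(t, bnd, SPEC_UNIT) == pytest.approx(
            expected, rel=1e-6
        )

    def test_increasing_boundary_rejected(self):
        with pytest.raises(ParameterError):
            fpt_survival_nonincreasing(1.0, Boundary("log", beta0=2.0), SPEC_UNIT)


class TestSimulator:
    def test_never_birth_probability_formula(self):
        # first step from y=1: l = e^{-A b} = e^{-3}
        path = simulate_path(SPEC_HALF, rng=_ScriptedRng([math.exp(-3.0) * 0.999]))
        assert path.terminated and len(path.birth_times) == 0

    def test_inverse_transform_first_birth(self):
        # U = 0.5 puts the first birth at Lambda^{-1}(log 2)
        path = simulate_path(SPEC_HALF, rng=_ScriptedRng([0.5, 1e-12]))
        expected = inverse_cumulative_intensity(math.log(2.0), SPEC_HALF)
        assert path.birth_times[0] == pytest.approx(expected, rel=1e-12)

    def test_reproducible_under_seed(self):
        p1 = simulate_path(SPEC_HALF, seed=123)
        p2 = simulate_path(SPEC_HALF, seed=123)
        np.testing.assert_array_equal(p1.birth_times, p2.birth_times)

    def test_birth_times_strictly_increasing(self):
        for seed in range(20):
            path = simulate_path(SPEC_HALF, seed=seed)
            assert np.all(np.diff(path.birth_times) > 0)

    def test_sample_mean_matches_theory(self):
        n = 10_000
        t_eval = 1.0
        counts = np.empty(n)
        for i in range(n):
            path = simulate_path(SPEC_HALF, rng=_path_rng(99, i))
            counts[i] = path.state_at(t_eval)
        mo = bp_moments(t_eval, SPEC_HALF)
        se = math.sqrt(mo.variance / n)
        assert abs(counts.mean() - mo.mean) < 3 * se

    def test_empirical_law_chi_square(self):
        """Simulated marginals agree with the negative-binomial law
        (chi-square GOF p > 0.01 at several times, fixed seed battery)."""
        n = 10_000
        paths = [simulate_path(SPEC_HALF, rng=_path_rng(7, i)) for i in range(n)]
        for t_eval in (0.5, 1.0, 2.0):
            states = np.array([p.state_at(t_eval) for p in paths])
            kmax = int(np.percentile(states, 99.5))
            observed = np.bincount(np.minimum(states, kmax + 1),
                                   minlength=kmax + 2)[1:]
            probs = np.array(
                [bp_transition_probability(k, t_eval, SPEC_HALF)
                 for k in range(1, kmax + 1)]
            )
            probs = np.append(probs, 1.0 - probs.sum())  # lumped tail
            stat, p_value = chisquare(observed, probs * n)
            assert p_value > 0.01, (t_eval, p_value)

    def test_paths_terminate_almost_surely(self):
        """Non-terminated paths at a long horizon are as rare as the
        residual intensity predicts: the chance that a path still has a
        (finite) birth after t_max is about E[X_inf] * (A b - Lambda(t_max)),
        which depends strongly on how fast the intensity tail closes."""
        n = 10_000
        # a = 0.5: the tail closes like t^-2, bound ~ 2e-3 at t_max = 1e3
        residual = SPEC_HALF.total_intensity - cumulative_intensity(1e3, SPEC_HALF)
        bound = math.exp(3.0) * residual
        not_terminated = sum(
            not simulate_path(SPEC_HALF, rng=_path_rng(11, i), t_max=1e3).terminated
            for i in range(n)
        )
        assert not_terminated / n < 3 * bound
        # a = 0.1: the tail closes like t^-10 and termination is essentially
        # certain by t_max = 1e3
        fast = BirthProcessSpec(GPDParams(1.0, 1.0, 0.1, 3.0), y=1)
        n_small = 2_000
        stuck = sum(
            not simulate_path(fast, rng=_path_rng(13, i), t_max=1e3).terminated
            for i in range(n_small)
        )
        assert stuck == 0
        assert math.exp(3.0) * (
            fast.total_intensity - cumulative_intensity(1e3, fast)
        ) < 1e-6


class TestFPTSimulate:
    def test_constant_boundary_against_analytic_cdf(self):
        """Empirical crossing CDF within Monte Carlo error of the
        integrated first-passage density."""
        k = 4
        bnd = Boundary("constant", level=float(k))
        est = fpt_simulate(bnd, SPEC_UNIT, n_paths=10_000, seed=21, t_max=60.0)
        for t in (1.0, 2.0, 5.0):
            analytic, _ = quad(lambda u: fpt_density(u, k, SPEC_UNIT), 0, t,
                               limit=400)
            empirical = np.mean(est.passage_times <= t) * est.crossing_ratio
            se = math.sqrt(analytic * (1 - analytic) / est.n_paths)
            assert abs(empirical - analytic) < 4 * se + 1e-3, t

    def test_crossing_ratio_limits_to_tail_mass(self):
        k = 4
        bnd = Boundary("constant", level=float(k))
        est = fpt_simulate(bnd, SPEC_UNIT, n_paths=10_000, seed=22, t_max=200.0)
        expected = fpt_mass(k, SPEC_UNIT)
        assert abs(est.crossing_ratio - expected) < 4 * est.crossing_se + 1e-3

    def test_histogram_accounts_for_every_crossing(self):
        bnd = Boundary("log", beta0=2.0)
        est = fpt_simulate(bnd, SPEC_HALF, n_paths=2000, seed=5, t_max=50.0)
        assert est.counts.sum() == round(est.crossing_ratio * est.n_paths)
        assert 0.0 <= est.crossing_ratio <= 1.0

    def test_equality_convention_is_rarer_than_attainment(self):
        bnd = Boundary("sinusoid", d=2.0, Q=5.0, beta0=7.0)
        att = fpt_simulate(bnd, SPEC_HALF, n_paths=3000, seed=9, t_max=50.0,
                           convention="attain")
        eq = fpt_simulate(bnd, SPEC_HALF, n_paths=3000, seed=9, t_max=50.0,
                          convention="equality")
        assert eq.crossing_ratio < att.crossing_ratio

    def test_path_streams_independent_of_n_paths(self):
        bnd = Boundary("constant", level=3.0)
        small = fpt_simulate(bnd, SPEC_UNIT, n_paths=50, seed=31, t_max=30.0)
        large = fpt_simulate(bnd, SPEC_UNIT, n_paths=200, seed=31, t_max=30.0)
        # the first 50 paths of the larger run are the entire smaller run
        crossed_small = sorted(small.passage_times)
        crossed_large_first50 = sorted(
            t for i, t in _crossings_by_index(bnd, SPEC_UNIT, 50, 31)
        )
        assert crossed_small == crossed_large_first50
        assert large.n_paths == 200


def _crossings_by_index(bnd, spec, n, seed):
    from gpdgrowth.birth_process import _first_crossing

    grid = np.arange(0.0, 30.0 + 0.01, 0.01)
    beta_grid = np.asarray(bnd(grid), dtype=float)
    out = []
    for i in range(n):
        path = simulate_path(spec, rng=_path_rng(seed, i), t_max=30.0)
        t = _first_crossing(path, bnd, grid, beta_grid, "attain")
        if t is not None:
            out.append((i, t))
    return out
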