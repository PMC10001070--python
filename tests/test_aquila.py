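"""Optimizer tests: each hunting-strategy update is checked against an
independently coded transcription of its equation, consuming random draws
in the documented order."""

import math

import numpy as np
import pytest
from scipy.special import gamma

from aquilens.aquila import (AAOConfig, Bounds, expanded_exploitation,
                             expanded_exploration, initialize, levy_flight,
                             levy_sigma, narrowed_exploitation,
                             narrowed_exploration, niche_sharing, optimize)
from aquilens.aquila import _spiral


# ----------------------------------------------------------- oracles

def oracle_sigma(beta):
    num = gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return (num / den) ** (1 / beta)


def oracle_levy(D, beta, scale, rng):
    u = rng.standard_normal(D)
    v = rng.standard_normal(D)
    return scale * u * oracle_sigma(beta) / np.abs(v) ** (1 / beta)


def oracle_x1(best, mean, t, T, rng):
    return best * (1 - t / T) + (mean - best) * rng.uniform()


def oracle_x2(best, other, r1, beta, scale, rng):
    D = best.size
    step = oracle_levy(D, beta, scale, rng)
    d1 = np.arange(1, D + 1)
    r = r1 + 0.00565 * d1
    theta = -0.005 * d1 + 3 * math.pi / 2
    y = r * np.cos(theta)
    x = r * np.sin(theta)
    return best * step + other + (y - x) * rng.uniform()


def oracle_x3(best, mean, lb, ub, alpha, delta, rng):
    r1 = rng.uniform()
    r2 = rng.uniform()
    return (best - mean) * alpha - r1 + ((ub - lb) * r2 + lb) * delta


def oracle_x4(pos, best, t, T, beta, scale, rng):
    D = pos.size
    qf = t ** ((2 * rng.uniform() - 1) / (1 - T) ** 2)
    g1 = 2 * rng.uniform() - 1
    g2 = 2 * (1 - t / T)
    step = oracle_levy(D, beta, scale, rng)
    return qf * best - g1 * pos * rng.uniform(size=D) - g2 * step


def oracle_sharing(positions, fitnesses, rho):
    """Brute-force pairwise sharing sums; multiplicative crowding penalty."""
    n = len(fitnesses)
    adjusted = np.empty(n)
    for i in range(n):
        total = 0.0
        for j in range(n):
            d = np.linalg.norm(positions[i] - positions[j])
            total += (1 - d / rho) if d < rho else 0.0
        f = fitnesses[i]
        adjusted[i] = f * total if f >= 0 else f / total
    return adjusted


# ------------------------------------------------------------- tests

class TestLevy:
    def test_sigma_matches_gamma_oracle(self):
        for beta in (0.5, 1.0, 1.5, 1.9):
            assert levy_sigma(beta) == pytest.approx(oracle_sigma(beta),
                                                     rel=1e-14)
        assert levy_sigma(1.5) == pytest.approx(0.6966, abs=1e-4)

    def test_zero_scale_gives_zero_vector(self):
        step = levy_flight(6, 1.5, 0.0, np.random.default_rng(0))
        assert np.array_equal(step, np.zeros(6))

    def test_tail_index_matches_stable_law(self):
        """Hill estimator on |steps| recovers the stability index β."""
        rng = np.random.default_rng(42)
        steps = np.abs(levy_flight(100_000, 1.5, 1.0, rng))
        top = np.sort(steps)[-500:]
        hill = 1.0 / np.mean(np.log(top[1:] / top[0]))
        assert hill == pytest.approx(1.5, abs=0.25)


class TestStrategyOracles:
    N_INSTANCES = 50

    def _instance(self, seed, D=4):
        rng = np.random.default_rng(seed)
        return (rng.normal(size=D), rng.normal(size=D), rng.normal(size=D),
                rng)

    @pytest.mark.parametrize("seed", range(N_INSTANCES))
    def test_expanded_exploration(self, seed):
        pos, best, mean, _ = self._instance(seed)
        t, T = seed % 10 + 1, 20
        got = expanded_exploration(pos, best, mean, t, T,
                                   np.random.default_rng(seed + 1000))
        want = oracle_x1(best, mean, t, T, np.random.default_rng(seed + 1000))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(N_INSTANCES))
    def test_narrowed_exploration(self, seed):
        pos, best, other, _ = self._instance(seed)
        got = narrowed_exploration(pos, best, other, 10.0, 1.5, 0.01,
                                   np.random.default_rng(seed + 2000))
        want = oracle_x2(best, other, 10.0, 1.5, 0.01,
                         np.random.default_rng(seed + 2000))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(N_INSTANCES))
    def test_expanded_exploitation(self, seed):
        pos, best, mean, _ = self._instance(seed)
        bounds = Bounds(-2 * np.ones(4), 3 * np.ones(4))
        got = expanded_exploitation(pos, best, mean, bounds, 0.1, 0.1,
                                    np.random.default_rng(seed + 3000))
        want = oracle_x3(best, mean, bounds.lower, bounds.upper, 0.1, 0.1,
                         np.random.default_rng(seed + 3000))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(N_INSTANCES))
    def test_narrowed_exploitation(self, seed):
        pos, best, _, _ = self._instance(seed)
        t, T = seed % 15 + 1, 20
        got = narrowed_exploitation(pos, best, t, T, 1.5, 0.01,
                                    np.random.default_rng(seed + 4000))
        want = oracle_x4(pos, best, t, T, 1.5, 0.01,
                         np.random.default_rng(seed + 4000))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_exploration_at_final_iteration_drops_best_term(self):
        best = np.array([2.0, -1.0])
        mean = np.array([0.5, 0.5])
        rng = np.random.default_rng(5)
        got = expanded_exploration(np.zeros(2), best, mean, 10, 10, rng)
        r = np.random.default_rng(5).uniform()
        np.testing.assert_allclose(got, (mean - best) * r)

    def test_converged_population_shrinks_toward_origin(self):
        best = np.array([1.0, 2.0])
        got = expanded_exploration(best, best, best, 3, 10,
                                   np.random.default_rng(0))
        np.testing.assert_allclose(got, best * (1 - 0.3))

    def test_spiral_theta_at_first_dimension(self):
        y, x = _spiral(3, r1=10.0)
        theta1 = -0.005 * 1 + 3 * math.pi / 2
        assert y[0] == pytest.approx((10.0 + 0.00565) * math.cos(theta1))
        assert x[0] == pytest.approx((10.0 + 0.00565) * math.sin(theta1))

    def test_exploitation_zero_box_and_equal_means(self):
        """With δ→0 weight of the box and X_best = X_M, X3 = −rand."""
        best = mean = np.ones(3)
        bounds = Bounds(np.zeros(3), np.zeros(3))
        got = expanded_exploitation(np.zeros(3), best, mean, bounds,
                                    0.5, 0.5, np.random.default_rng(8))
        r = np.random.default_rng(8).uniform()
        np.testing.assert_allclose(got, -r * np.ones(3))

    def test_swoop_levy_term_vanishes_at_final_iteration(self):
        pos, best = np.ones(3), 2 * np.ones(3)
        got = narrowed_exploitation(pos, best, 10, 10, 1.5, 0.01,
                                    np.random.default_rng(9))
        rng = np.random.default_rng(9)
        qf = 10.0 ** ((2 * rng.uniform() - 1) / 81)
        g1 = 2 * rng.uniform() - 1
        rng.standard_normal(3)
        rng.standard_normal(3)
        r = rng.uniform(size=3)
        np.testing.assert_allclose(got, qf * best - g1 * pos * r)


class TestNicheSharing:
    def test_isolated_niches_unchanged(self):
        pos = np.array([[0.0], [10.0], [20.0]])
        fit = np.array([3.0, 1.0, 2.0])
        adjusted = niche_sharing(pos, fit, rho=1.0)
        np.testing.assert_allclose(adjusted, fit)

    def test_coincident_pair_shares_fully(self):
        pos = np.array([[1.0], [1.0]])
        fit = np.array([4.0, 6.0])
        adjusted = niche_sharing(pos, fit, rho=0.5)
        # each sees sh(0)=1 from itself and the other: sharing sum 2;
        # the best is exempt, the other is penalised
        assert adjusted[0] == 4.0
        assert adjusted[1] == 12.0

    def test_matches_brute_force_oracle(self):
        pos = np.array([[0.0], [0.4], [0.9], [3.0]])
        fit = np.array([5.0, 2.0, 7.0, 4.0])
        adjusted = niche_sharing(pos, fit, rho=1.0)
        want = oracle_sharing(pos, fit, rho=1.0)
        best = int(np.argmin(fit))
        want[best] = fit[best]
        np.testing.assert_allclose(adjusted, want)

    def test_penalty_never_improves_fitness(self):
        rng = np.random.default_rng(11)
        pos = rng.normal(size=(8, 3))
        fit = rng.normal(size=8)  # mixed signs
        adjusted = niche_sharing(pos, fit, rho=5.0)
        assert (adjusted >= fit - 1e-12).all()

    def test_best_rank_never_worsened(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = rng.normal(size=(6, 2))
            fit = rng.uniform(1, 10, 6)
            adjusted = niche_sharing(pos, fit, rho=2.0)
            # the incumbent best always attains the minimal adjusted value
            assert adjusted[np.argmin(fit)] == adjusted.min()

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            niche_sharing(np.zeros((2, 1)), np.ones(2), rho=0.0)


class TestOptimize:
    def test_initialize_uniform_within_bounds(self):
        b = Bounds(np.zeros(5), np.ones(5))
        X = initialize(b, 30, np.random.default_rng(0))
        assert X.shape == (30, 5)
        assert (X >= 0).all() and (X <= 1).all()

    def test_zero_width_box_collapses(self):
        b = Bounds(2.5 * np.ones(3), 2.5 * np.ones(3))
        X = initialize(b, 4, np.random.default_rng(1))
        assert np.allclose(X, 2.5)

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError):
            initialize(Bounds([0.0], [1.0]), 1, np.random.default_rng(0))
        with pytest.raises(ValueError):
            AAOConfig(population_size=1)

    def test_sphere_converges(self):
        b = Bounds(-5 * np.ones(5), 5 * np.ones(5))
        vals = []
        for seed in range(5):
            cfg = AAOConfig(population_size=20, max_iterations=100, seed=seed)
            _, f, _ = optimize(lambda x: float((x**2).sum()), b, cfg)
            vals.append(f)
        assert np.median(vals) < 1e-2

    def test_elitist_monotonicity_and_bounds(self):
        b = Bounds(np.array([-2.0, -2.0]), np.array([2.0, 2.0]))
        cfg = AAOConfig(population_size=10, max_iterations=40, seed=7)
        x, f, trace = optimize(
            lambda x: float(np.sin(3 * x[0]) + x[1] ** 2), b, cfg)
        assert all(np.diff(trace.best_fitness) <= 0)
        assert b.contains(x)
        for p in trace.best_position:
            assert b.contains(p)

    def test_seed_determinism(self):
        b = Bounds(-np.ones(3), np.ones(3))
        cfg = AAOConfig(population_size=8, max_iterations=15, seed=3)
        r1 = optimize(lambda x: float((x**2).sum()), b, cfg)
        r2 = optimize(lambda x: float((x**2).sum()), b, cfg)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[2].best_fitness == r2[2].best_fitness

    def test_single_iteration_trace(self):
        b = Bounds([0.0], [1.0])
        cfg = AAOConfig(population_size=2, max_iterations=1, seed=0)
        _, f, trace = optimize(lambda x: float(x[0]), b, cfg)
        assert len(trace) == 1
        assert f <= 1.0

    def test_constant_objective(self):
        b = Bounds(-np.ones(2), np.ones(2))
        cfg = AAOConfig(population_size=5, max_iterations=10, seed=1)
        _, f, _ = optimize(lambda x: 3.25, b, cfg)
        assert f == 3.25

    def test_nonfinite_objective_rejected_with_warning(self):
        b = Bounds([0.0], [1.0])
        cfg = AAOConfig(population_size=4, max_iterations=5, seed=2)

        def spiky(x):
            return float("nan") if x[0] > 0.5 else float(x[0])

        with pytest.warns(UserWarning):
            _, f, _ = optimize(spiky, b, cfg)
        assert np.isfinite(f)

    def test_trace_csv_export(self, tmp_path):
        b = Bounds([0.0], [1.0])
        cfg = AAOConfig(population_size=4, max_iterations=5, seed=0)
        _, _, trace = optimize(lambda x: float(x[0]), b, cfg)
        trace.to_csv(tmp_path / "trace.csv")
        df = trace.to_frame()
        assert len(df) == 5
        strategy_cols = [c for c in df.columns if c.startswith("n_")]
        assert (df[strategy_cols].sum(axis=1) == 4).all()
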