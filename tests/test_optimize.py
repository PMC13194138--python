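import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegselect.benchmarks import benchmark_suite
from eegselect.optimize import (OptimizerConfig, SearchSpace, binarize_position,
                                chaotic_init, convergence_factor,
                                encircle_update, hybrid_spiral_update,
                                leader_weights, logistic_iterates, perturb,
                                population_diversity, reflect_bounds,
                                run_optimizer, spiral_update)


def sphere_space(dim=5, bound=10.0):
    return SearchSpace(dim=dim, lower=-bound, upper=bound,
                       objective=lambda x: float(np.sum(x ** 2)))


class TestPrimitives:
    def test_logistic_map_iterates(self):
        np.testing.assert_allclose(logistic_iterates(0.7, 2), [0.84, 0.5376],
                                   atol=1e-12)

    def test_chaotic_init_within_bounds_and_deterministic(self):
        space = sphere_space()
        a = chaotic_init(20, space, seed=5)
        b = chaotic_init(20, space, seed=5)
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= space.lower) and np.all(a <= space.upper)
        c = chaotic_init(20, space, seed=6)
        assert not np.array_equal(a, c)

    def test_tent_map_variant_in_bounds(self):
        space = sphere_space()
        a = chaotic_init(10, space, seed=1, chaotic_map="tent")
        assert np.all(a >= space.lower) and np.all(a <= space.upper)

    @pytest.mark.parametrize("t,T,mode,expect", [
        (0, 300, "printed_eq45", 2.0),
        (150, 300, "printed_eq45", 1.5),
        (300, 300, "printed_eq45", 2.0),
        (0, 300, "linear", 2.0),
        (300, 300, "linear", 0.0),
    ])
    def test_convergence_factor(self, t, T, mode, expect):
        assert convergence_factor(t, T, mode) == pytest.approx(expect)

    def test_convergence_factor_bad_T(self):
        with pytest.raises(ValueError):
            convergence_factor(0, 0)

    def test_encircle_fixed_point_and_hand_case(self):
        best = np.array([0.0, 0.0])
        # D = |C X* - X*| with X = X*, C = 1 -> unchanged
        np.testing.assert_allclose(encircle_update(best, best, 0.7, 1.0), best)
        got = encircle_update(best, np.array([2.0, 0.0]), 0.5, 1.0)
        np.testing.assert_allclose(got, [-1.0, 0.0])

    def test_spiral_fixed_point(self):
        best = np.array([1.5, -2.0])
        np.testing.assert_allclose(spiral_update(best, best, b=1.0, l=0.0), best)

    def test_hybrid_spiral_hand_cases(self):
        zero = np.zeros(2)
        x = np.ones(2)
        np.testing.assert_allclose(
            hybrid_spiral_update(x, zero, zero, C=1.0, b=1.0, l=0.0), [1.0, 1.0])
        got = hybrid_spiral_update(x, zero, zero, C=1.0, b=1.0, l=0.5)
        np.testing.assert_allclose(got, [-math.exp(0.5)] * 2, atol=1e-12)
        # X = X_best = X_alpha with C = 1: zero spiral term plus midpoint X
        np.testing.assert_allclose(
            hybrid_spiral_update(x, x, x, C=1.0, b=1.0, l=0.3), x)

    def test_leader_weights_hand_case_and_degeneracy(self):
        raw = leader_weights([2.0], 1.0, 3.0, normalize=False)
        assert raw[0] == pytest.approx(0.5)
        np.testing.assert_allclose(leader_weights([1.0, 1.0, 1.0], 1.0, 1.0),
                                   np.full(3, 1 / 3))
        w = leader_weights([1.0, 2.0, 3.0], 1.0, 3.0)
        assert w.sum() == pytest.approx(1.0)

    def test_binarize_strict_threshold(self):
        np.testing.assert_array_equal(binarize_position([0.3, -0.2]), [1, 0])
        np.testing.assert_array_equal(binarize_position([0.0, 1e-12]), [0, 1])
        np.testing.assert_array_equal(binarize_position([-1.0, -0.1]), [0, 0])

    def test_diversity_cases(self):
        space = sphere_space(dim=3, bound=1.0)
        same = np.zeros((4, 3))
        assert population_diversity(same, space) == 0.0
        corners = np.vstack([space.lower, space.upper])
        assert population_diversity(corners, space) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            population_diversity(np.zeros((1, 3)), space)

    def test_diversity_translation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (6, 3))
        a = SearchSpace(3, -2.0, 2.0, lambda x: 0.0)
        b = SearchSpace(3, -1.0, 3.0, lambda x: 0.0)
        assert population_diversity(pts, a) == pytest.approx(
            population_diversity(pts + 1.0, b))

    @settings(max_examples=50, deadline=None, database=None, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=3))
    def test_reflection_always_lands_inside(self, coords):
        lo = np.array([-10.0, 0.0, 5.0])
        hi = np.array([10.0, 1.0, 6.0])
        y = reflect_bounds(np.array(coords), lo, hi)
        assert np.all(y >= lo - 1e-9) and np.all(y <= hi + 1e-9)

    def test_reflection_identity_inside(self):
        lo, hi = np.array([-1.0]), np.array([1.0])
        np.testing.assert_allclose(reflect_bounds(np.array([0.3]), lo, hi), [0.3])
        np.testing.assert_allclose(reflect_bounds(np.array([1.4]), lo, hi), [0.6])


class TestPerturb:
    def test_elitism_and_counts(self):
        space = sphere_space(dim=2, bound=1.0)
        rng = np.random.default_rng(0)
        pos = np.tile(np.linspace(0, 0.9, 10)[:, None], (1, 2))
        fit = np.array([space.evaluate(p) for p in pos])
        new, victims = perturb(pos, fit, space, rng, fraction=1.0)
        assert len(victims) == 9
        assert 0 not in victims  # the best individual is kept
        np.testing.assert_array_equal(new[0], pos[0])

    def test_ceil_rule_redraws_at_least_one(self):
        space = sphere_space(dim=2, bound=1.0)
        rng = np.random.default_rng(1)
        pos = np.zeros((8, 2))
        fit = np.arange(8.0)
        _, victims = perturb(pos, fit, space, rng, fraction=1e-6)
        assert len(victims) == 1

    def test_redrawn_positions_in_bounds(self):
        space = sphere_space(dim=4, bound=3.0)
        rng = np.random.default_rng(2)
        for _ in range(200):
            pos = rng.uniform(-3, 3, (6, 4))
            fit = rng.random(6)
            new, _ = perturb(pos, fit, space, rng, fraction=0.5)
            assert np.all(new >= space.lower) and np.all(new <= space.upper)


@pytest.mark.parametrize("algorithm", ["woa", "gwo", "woa_gwo"])
class TestDrivers:
    def test_curves_monotone_and_lengths(self, algorithm):
        space = sphere_space()
        cfg = OptimizerConfig(pop_size=12, max_iter=40, seed=0)
        res = run_optimizer(space, cfg, algorithm)
        assert len(res.convergence_curve) == 40
        assert len(res.diversity_curve) == 40
        assert np.all(np.diff(res.convergence_curve) <= 1e-15)
        assert res.best_fitness == res.convergence_curve[-1]

    def test_same_seed_bit_identical(self, algorithm):
        space = sphere_space()
        cfg = OptimizerConfig(pop_size=10, max_iter=25, seed=3)
        r1 = run_optimizer(space, cfg, algorithm)
        r2 = run_optimizer(sphere_space(), cfg, algorithm)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.convergence_curve, r2.convergence_curve)
        assert r1.evaluations == r2.evaluations

    def test_best_position_within_bounds(self, algorithm):
        space = sphere_space(dim=3, bound=2.0)
        for seed in range(5):
            res = run_optimizer(space, OptimizerConfig(pop_size=8, max_iter=15,
                                                       seed=seed), algorithm)
            assert np.all(res.best_position >= space.lower - 1e-9)
            assert np.all(res.best_position <= space.upper + 1e-9)

    def test_finds_reasonable_sphere_minimum(self, algorithm):
        space = sphere_space(dim=5, bound=10.0)
        res = run_optimizer(space, OptimizerConfig(pop_size=20, max_iter=100,
                                                   seed=1), algorithm)
        assert res.best_fitness < 1.0


class TestDriverOptions:
    def test_maximize_negates_internally(self):
        space = SearchSpace(2, -1.0, 1.0, lambda x: -float(np.sum(x ** 2)),
                            maximize=True)
        res = run_optimizer(space, OptimizerConfig(pop_size=8, max_iter=20,
                                                   seed=0), "woa_gwo")
        assert res.best_value == -res.best_fitness
        assert res.best_value <= 0.0

    def test_linear_mode_and_no_chaos_still_converge(self):
        space = sphere_space()
        cfg = OptimizerConfig(pop_size=12, max_iter=50, seed=2,
                              convergence_mode="linear", chaotic_map="none")
        res = run_optimizer(space, cfg, "woa_gwo")
        assert res.best_fitness < 1.0

    def test_objective_error_carries_context(self):
        def bad(x):
            raise RuntimeError("boom")

        space = SearchSpace(2, -1.0, 1.0, bad)
        with pytest.raises(RuntimeError):
            run_optimizer(space, OptimizerConfig(pop_size=4, max_iter=2, seed=0),
                          "woa_gwo")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=2)
        with pytest.raises(ValueError):
            OptimizerConfig(perturb_fraction=0.0)
        with pytest.raises(ValueError):
            SearchSpace(2, 1.0, -1.0, lambda x: 0.0)
        with pytest.raises(ValueError):
            run_optimizer(sphere_space(), OptimizerConfig(), "simplex")
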