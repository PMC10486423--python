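"""Gray wolf optimizer: determinism, schedules, update rules, convergence."""

import numpy as np
import pytest

from lesionselect.gwo import (
    GWOConfig,
    coefficients,
    encircle_distance,
    init_pack,
    leader_guided_position,
    optimize,
    rastrigin,
    sphere,
    step,
)


class TestConfigAndInit:
    def test_too_few_wolves_rejected(self):
        with pytest.raises(ValueError, match="n_wolves"):
            GWOConfig(n_wolves=3)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            GWOConfig(bounds=(1.0, 1.0)).bounds_array(2)

    def test_seeded_init_is_reproducible(self):
        cfg = GWOConfig(n_wolves=10, n_iterations=5, bounds=(-1, 1), seed=7)
        s1 = init_pack(cfg, 2, sphere)
        s2 = init_pack(cfg, 2, sphere)
        np.testing.assert_array_equal(s1.positions, s2.positions)

    def test_alpha_is_pack_minimum_on_sphere(self):
        cfg = GWOConfig(n_wolves=30, n_iterations=5, bounds=(-5, 5), seed=0)
        state = init_pack(cfg, 3, sphere, sense="minimize")
        assert state.alpha[1] == pytest.approx(min(sphere(x) for x in state.positions))

    def test_leader_ordering(self):
        cfg = GWOConfig(n_wolves=12, n_iterations=5, bounds=(-5, 5), seed=2)
        state = init_pack(cfg, 2, sphere)
        assert state.alpha[1] <= state.beta[1] <= state.delta[1]

    def test_non_finite_objective_names_wolf(self):
        cfg = GWOConfig(n_wolves=4, n_iterations=1, bounds=(-1, 1), seed=0)
        with pytest.raises(ValueError, match="wolf 0"):
            init_pack(cfg, 2, lambda x: float("inf"))


class TestCoefficients:
    def test_zero_control_scalar_gives_zero_A(self):
        rng = np.random.default_rng(0)
        A, _ = coefficients(0.0, 5, rng)
        np.testing.assert_array_equal(A, np.zeros(5))

    def test_closed_form_midpoint(self):
        # A = 2·a·r1 − a vanishes when r1 = 0.5
        class HalfRng:
            def random(self, n):
                return np.full(n, 0.5)

        A, C = coefficients(1.0, 3, HalfRng())
        np.testing.assert_allclose(A, 0.0)
        np.testing.assert_allclose(C, 1.0)

    def test_empirical_ranges(self):
        rng = np.random.default_rng(3)
        draws = [coefficients(2.0, 1, rng) for _ in range(10_000)]
        A = np.array([a[0] for a, _ in draws])
        C = np.array([c[0] for _, c in draws])
        assert A.min() >= -2.0 and A.max() <= 2.0
        assert C.min() >= 0.0 and C.max() <= 2.0


class TestEncircleDistance:
    def test_prey_equals_wolf_with_unit_C(self):
        p = np.array([1.0, -2.0])
        np.testing.assert_array_equal(encircle_distance(np.ones(2), p, p), np.zeros(2))

    def test_hand_evaluation(self):
        out = encircle_distance(np.array([2.0]), np.array([1.0]), np.array([0.0]))
        np.testing.assert_array_equal(out, np.array([2.0]))

    def test_non_negative_for_random_triples(self, rng):
        for _ in range(100):
            C, prey, wolf = rng.normal(size=(3, 4))
            assert (encircle_distance(np.abs(C), prey, wolf) >= 0).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            encircle_distance(np.ones(2), np.ones(3), np.ones(3))


class TestPositionUpdate:
    def _converged_state(self, point):
        cfg = GWOConfig(n_wolves=4, n_iterations=1, bounds=(-5, 5), seed=0)
        state = init_pack(cfg, point.size, sphere)
        state.alpha = state.beta = state.delta = (point, 0.0)
        state.a = 0.0
        return state

    def test_fixed_point_when_leaders_agree_and_a_zero(self):
        point = np.array([0.5, -1.5])
        state = self._converged_state(point)
        new = leader_guided_position(state, np.array([3.0, 3.0]))
        np.testing.assert_allclose(new, point)

    def test_clamped_to_bounds(self):
        cfg = GWOConfig(n_wolves=6, n_iterations=3, bounds=(-1, 1), seed=5)
        state = init_pack(cfg, 3, sphere)
        for _ in range(100):
            new = leader_guided_position(state, state.rng.uniform(-1, 1, 3))
            assert (new >= -1).all() and (new <= 1).all()

    def test_seeded_update_is_deterministic(self):
        cfg = GWOConfig(n_wolves=6, n_iterations=3, bounds=(-1, 1), seed=5)
        state = init_pack(cfg, 2, sphere)
        wolf = np.array([0.2, -0.2])
        a = leader_guided_position(state, wolf, rng=np.random.default_rng(9))
        b = leader_guided_position(state, wolf, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestStepAndOptimize:
    def test_step_monotone_and_counts(self):
        cfg = GWOConfig(n_wolves=20, n_iterations=50, bounds=(-5, 5), seed=11)
        state = init_pack(cfg, 3, sphere)
        best = state.best_fitness
        for i in range(50):
            step(state, sphere)
            assert state.best_fitness <= best
            assert state.alpha[1] <= state.beta[1] <= state.delta[1]
            best = state.best_fitness
            assert state.iteration == i + 1
        assert state.a == pytest.approx(0.0, abs=1e-12)

    def test_control_scalar_decays_linearly(self):
        cfg = GWOConfig(n_wolves=5, n_iterations=4, bounds=(-1, 1), seed=0)
        state = init_pack(cfg, 1, sphere)
        observed = [state.a]
        for _ in range(4):
            step(state, sphere)
            observed.append(state.a)
        np.testing.assert_allclose(observed, [2.0, 1.5, 1.0, 0.5, 0.0])

    def test_sphere_convergence(self):
        cfg = GWOConfig(n_wolves=30, n_iterations=200, bounds=(-5.12, 5.12), seed=3)
        result = optimize(cfg, 2, sphere)
        assert result.best_fitness < 1e-4

    def test_constant_objective(self):
        cfg = GWOConfig(n_wolves=5, n_iterations=10, bounds=(-1, 1), seed=4)
        result = optimize(cfg, 2, lambda x: 7.5)
        assert result.best_fitness == 7.5

    def test_trace_length_and_monotonicity(self):
        cfg = GWOConfig(n_wolves=10, n_iterations=30, bounds=(-5, 5), seed=8)
        result = optimize(cfg, 2, sphere)
        assert len(result.trace) == 31
        assert (np.diff(result.trace) <= 0).all()

    def test_bit_reproducible_runs(self):
        cfg = GWOConfig(n_wolves=10, n_iterations=20, bounds=(-5, 5), seed=13)
        r1 = optimize(cfg, 3, rastrigin)
        r2 = optimize(cfg, 3, rastrigin)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_maximization_sense(self):
        cfg = GWOConfig(n_wolves=10, n_iterations=50, bounds=(-2, 2), seed=1)
        result = optimize(cfg, 2, lambda x: -sphere(x), sense="maximize")
        assert result.best_fitness == pytest.approx(0.0, abs=1e-4)
        assert (np.diff(result.trace) >= 0).all()

    def test_literal_update_variant_stays_non_negative_at_origin_problem(self):
        # the nested-absolute-value rule confines coordinates near |leader|
        cfg = GWOConfig(n_wolves=10, n_iterations=50, bounds=(-5, 5), seed=2)
        result = optimize(cfg, 2, sphere, literal_update=True)
        assert np.isfinite(result.best_fitness)
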