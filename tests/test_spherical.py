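"""Spherical-search optimizer: projection laws, adaptation, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sphelm import spherical as ss


def quadratic_config(**kw):
    defaults = dict(nfes_max=2000, pop_init=30, pop_min=4, memory_size=5, seed=0,
                    lower=-5.0, upper=5.0)
    defaults.update(kw)
    return ss.SSConfig(**defaults)


class TestInitPopulation:
    def test_zero_width_bounds_degenerate(self):
        cfg = ss.SSConfig(lower=2.0, upper=2.0, pop_init=10, seed=0)
        state = ss.init_population(ss.sphere, 3, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(state.population, 2.0)
        assert state.nfes == 10

    def test_same_seed_identical(self):
        cfg = ss.SSConfig(pop_init=20, seed=5)
        a = ss.init_population(ss.sphere, 4, cfg, np.random.default_rng(5))
        b = ss.init_population(ss.sphere, 4, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a.population, b.population)

    def test_uniform_mean_within_three_sigma(self):
        cfg = ss.SSConfig(pop_init=10_000, lower=-1.0, upper=3.0, seed=0)
        state = ss.init_population(lambda x: 0.0, 1, cfg, np.random.default_rng(0))
        vals = state.population.ravel()
        width = 4.0
        se = width / np.sqrt(12) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 3 * se
        assert vals.min() > -1.0 and vals.max() <= 3.0  # open-low, closed-high


class TestProjection:
    def test_full_rank_is_identity(self, rng):
        m = ss.make_projection(6, 6, rng)
        np.testing.assert_allclose(m, np.eye(6), atol=1e-9)

    @pytest.mark.parametrize("dim,rank", [(5, 1), (10, 4), (20, 19), (7, 3)])
    def test_symmetric_idempotent_trace(self, dim, rank, rng):
        m = ss.make_projection(dim, rank, rng)
        np.testing.assert_allclose(m, m.T, atol=1e-9)
        np.testing.assert_allclose(m @ m, m, atol=1e-9)
        assert np.trace(m) == pytest.approx(rank, abs=1e-9)

    def test_eigenvalues_are_zeros_and_ones(self, rng):
        dim, rank = 12, 5
        m = ss.make_projection(dim, rank, rng)
        eig = np.sort(np.linalg.eigvalsh(m))
        np.testing.assert_allclose(eig[: dim - rank], 0.0, atol=1e-8)
        np.testing.assert_allclose(eig[dim - rank :], 1.0, atol=1e-8)

    def test_rank_out_of_range(self, rng):
        with pytest.raises(ValueError, match="rank"):
            ss.make_projection(5, 0, rng)
        with pytest.raises(ValueError, match="rank"):
            ss.make_projection(5, 6, rng)


class TestControlParams:
    def _state(self, N, D, rank_prob, step):
        memory = np.vstack([np.full(5, rank_prob), np.full(5, step)])
        return ss.SSState(np.zeros((N, D)), np.zeros(N), memory)

    def test_prob_one_always_clamps_to_dim_minus_one(self):
        state = self._state(50, 8, 1.0, 0.7)
        ranks, _ = ss.sample_control_params(state, ss.SSConfig(), np.random.default_rng(0))
        assert np.all(ranks == 7)

    def test_binomial_mean_within_three_sigma(self):
        D, n = 40, 10_000
        state = self._state(n, D, 0.5, 0.7)
        ranks, _ = ss.sample_control_params(state, ss.SSConfig(), np.random.default_rng(1))
        se = np.sqrt(D * 0.25 / n)
        assert abs(ranks.mean() - 20.0) < 3 * se

    def test_step_sizes_in_unit_interval(self):
        state = self._state(5000, 10, 0.5, 0.7)
        _, cs = ss.sample_control_params(state, ss.SSConfig(), np.random.default_rng(2))
        assert np.all(cs > 0.0) and np.all(cs <= 1.0)


class TestTrialSolution:
    def _state(self, rng, N=6, D=4):
        pop = rng.standard_normal((N, D))
        fit = rng.random(N)
        memory = np.vstack([np.full(5, 0.5), np.full(5, 0.7)])
        return ss.SSState(pop, fit, memory)

    def test_zero_step_size_returns_parent(self, rng):
        state = self._state(rng)
        m = ss.make_projection(4, 2, rng)
        cfg = ss.SSConfig(lower=-100, upper=100)
        y = ss.trial_solution(state, 0, 0.0, m, True, cfg, rng)
        np.testing.assert_allclose(y, state.population[0])

    def test_identical_population_gives_zero_direction(self, rng):
        state = self._state(rng)
        state.population[:] = state.population[0]
        m = ss.make_projection(4, 2, rng)
        cfg = ss.SSConfig(lower=-100, upper=100)
        y = ss.trial_solution(state, 0, 0.9, m, True, cfg, rng)
        np.testing.assert_allclose(y, state.population[0], atol=1e-12)

    def test_step_lies_in_projection_subspace(self, rng):
        state = self._state(rng)
        m = ss.make_projection(4, 2, rng)
        cfg = ss.SSConfig(lower=-1e9, upper=1e9)  # wide: no repair
        for direction in (True, False):
            y = ss.trial_solution(state, 1, 0.8, m, direction, cfg, rng)
            step = y - state.population[1]
            np.testing.assert_allclose(m @ step, step, atol=1e-9)

    def test_bound_repair_midpoint(self):
        lower, upper = np.array([0.0]), np.array([1.0])
        x = np.array([0.8])
        assert ss.repair_bounds(np.array([1.6]), x, lower, upper)[0] == pytest.approx(0.9)
        assert ss.repair_bounds(np.array([-0.4]), x, lower, upper)[0] == pytest.approx(0.4)

    def test_too_small_population_raises(self, rng):
        state = self._state(rng, N=3)
        m = ss.make_projection(4, 2, rng)
        with pytest.raises(ValueError, match="population"):
            ss.trial_solution(state, 0, 0.5, m, True, ss.SSConfig(), rng)


class TestDirections:
    def test_even_split(self):
        mask = ss.assign_directions(np.array([3.0, 1.0, 4.0, 2.0]))
        assert mask.sum() == 2
        assert mask[1] and mask[3]  # the two best are towards-rand

    def test_odd_population_median_goes_towards_best(self):
        mask = ss.assign_directions(np.array([5.0, 1.0, 3.0, 2.0, 4.0]))
        assert mask.sum() == 2  # N=5 -> 2 towards-rand, 3 towards-best

    def test_all_equal_fitness_splits_by_index(self):
        mask = ss.assign_directions(np.zeros(6))
        np.testing.assert_array_equal(mask, [True, True, True, False, False, False])


class TestGreedySelect:
    def _state(self, pop, fit):
        memory = np.vstack([np.full(5, 0.5), np.full(5, 0.7)])
        state = ss.SSState(np.array(pop, dtype=float), np.array(fit, dtype=float), memory)
        state.track_best()
        return state

    def test_equal_fitness_trial_accepted(self):
        state = self._state([[0.0]] * 4, [1.0] * 4)
        trials = np.full((4, 1), 9.0)
        succ = ss.greedy_select(state, trials, np.array([1.0, 2.0, 1.0, 2.0]),
                                np.arange(4.0), np.full(4, 0.5))
        np.testing.assert_array_equal(state.population.ravel(), [9.0, 0.0, 9.0, 0.0])
        assert len(succ["weights"]) == 2 and np.all(succ["weights"] == 0.0)

    def test_all_worse_leaves_population_unchanged(self):
        state = self._state([[0.0]] * 4, [1.0] * 4)
        succ = ss.greedy_select(state, np.full((4, 1), 9.0), np.full(4, 5.0),
                                np.arange(4.0), np.full(4, 0.5))
        np.testing.assert_array_equal(state.population, 0.0)
        assert len(succ["weights"]) == 0

    def test_best_so_far_monotone_over_random_steps(self, rng):
        state = self._state(rng.standard_normal((10, 1)), rng.random(10))
        for _ in range(100):
            best_before = state.best_f
            trials = rng.standard_normal((10, 1))
            ss.greedy_select(state, trials, rng.random(10),
                             rng.integers(1, 5, 10).astype(float), rng.random(10))
            assert state.best_f <= best_before


class TestMemory:
    def _state(self, D=10, H=5):
        memory = np.vstack([np.full(H, 0.5), np.full(H, 0.7)])
        return ss.SSState(np.zeros((4, D)), np.zeros(4), memory)

    def test_single_success_sets_cell_to_value(self):
        state = self._state(D=10)
        ss.update_memory(state, {"ranks": np.array([4.0]), "cs": np.array([0.3]),
                                 "weights": np.array([1.0])})
        assert state.memory[0, 0] == pytest.approx(0.4)  # rank/D
        assert state.memory[1, 0] == pytest.approx(0.3)
        assert state.memory_cursor == 1

    def test_two_equal_weight_successes_lehmer(self):
        state = self._state(D=1)
        ss.update_memory(state, {"ranks": np.array([0.2, 0.8]), "cs": np.array([0.2, 0.8]),
                                 "weights": np.array([1.0, 1.0])})
        # (0.04 + 0.64) / (0.2 + 0.8) = 0.68
        assert state.memory[1, 0] == pytest.approx(0.68)

    def test_no_successes_leaves_memory_unchanged(self):
        state = self._state()
        before = state.memory.copy()
        ss.update_memory(state, {"ranks": np.array([]), "cs": np.array([]),
                                 "weights": np.array([])})
        np.testing.assert_array_equal(state.memory, before)
        assert state.memory_cursor == 0

    def test_cursor_wraps_cyclically(self):
        state = self._state(H=2)
        succ = {"ranks": np.array([5.0]), "cs": np.array([0.5]), "weights": np.array([1.0])}
        for _ in range(3):
            ss.update_memory(state, succ)
        assert state.memory_cursor == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.01, 1.0), st.floats(0.01, 1.0)),
                    min_size=1, max_size=10))
    def test_lehmer_mean_dominates_arithmetic_mean(self, pairs):
        values = np.array([p[0] for p in pairs])
        weights = np.array([p[1] for p in pairs])
        w = weights / weights.sum()
        lehmer = np.sum(w * values**2) / np.sum(w * values)
        assert lehmer >= np.sum(w * values) - 1e-12


class TestReduction:
    def test_schedule_endpoints(self):
        cfg = ss.SSConfig(nfes_max=10_000, pop_init=100, pop_min=4)
        assert ss.population_schedule(0, cfg) == 100
        assert ss.population_schedule(10_000, cfg) == 4

    def test_exponential_schedule_endpoints(self):
        cfg = ss.SSConfig(nfes_max=1000, pop_init=64, pop_min=4, reduction="exponential")
        assert ss.population_schedule(0, cfg) == 64
        assert ss.population_schedule(1000, cfg) == 4
        assert ss.population_schedule(500, cfg) == 16  # geometric midpoint

    def test_size_sequence_non_increasing_over_run(self):
        cfg = quadratic_config(nfes_max=1500, pop_init=40)
        result = ss.optimize(ss.sphere, 5, cfg)
        sizes = result.trace["pop_size"].to_numpy()
        assert (np.diff(sizes) <= 0).all()
        assert sizes[-1] == cfg.pop_min


class TestOptimize:
    def test_sphere_converges(self):
        cfg = ss.SSConfig(nfes_max=10_000, lower=-5, upper=5, seed=1)
        result = ss.optimize(ss.sphere, 10, cfg)
        assert result.best_f < 1e-2
        assert result.nfes == 10_000

    def test_constant_objective_no_crash(self):
        cfg = quadratic_config(nfes_max=500, pop_init=10)
        result = ss.optimize(lambda x: 7.5, 3, cfg)
        assert result.best_f == 7.5

    def test_same_seed_identical_trace(self):
        cfg = quadratic_config(nfes_max=800, pop_init=20, seed=9)
        a = ss.optimize(ss.rastrigin, 4, cfg)
        b = ss.optimize(ss.rastrigin, 4, cfg)
        assert a.trace.equals(b.trace)
        np.testing.assert_array_equal(a.best_x, b.best_x)

    def test_best_so_far_monotone(self):
        result = ss.optimize(ss.rosenbrock, 6, quadratic_config(seed=2))
        assert (np.diff(result.trace["best_value"]) <= 1e-15).all()

    def test_population_stays_in_bounds(self):
        cfg = quadratic_config(nfes_max=600, pop_init=15, lower=-2.0, upper=2.0, seed=3)
        result = ss.optimize(ss.rastrigin, 5, cfg)
        assert result.state.population.min() >= -2.0
        assert result.state.population.max() <= 2.0

    def test_non_finite_objective_warns_and_continues(self):
        calls = {"n": 0}

        def nasty(x):
            calls["n"] += 1
            return np.nan if calls["n"] % 7 == 0 else ss.sphere(x)

        cfg = quadratic_config(nfes_max=300, pop_init=10)
        with pytest.warns(UserWarning, match="non-finite"):
            result = ss.optimize(nasty, 3, cfg)
        assert np.isfinite(result.best_f)

    def test_beats_pure_random_search_on_quadratic(self):
        """Paired over 10 seeds with the same budget, SS should dominate
        uniform random sampling on a separable quadratic."""
        wins = 0
        for seed in range(10):
            cfg = ss.SSConfig(nfes_max=1500, pop_init=30, lower=-5, upper=5, seed=seed)
            ss_best = ss.optimize(ss.sphere, 8, cfg).best_f
            rng = np.random.default_rng(seed)
            samples = rng.uniform(-5, 5, size=(1500, 8))
            rs_best = np.square(samples).sum(axis=1).min()
            if ss_best < rs_best:
                wins += 1
        assert wins == 10
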