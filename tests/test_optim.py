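"""Unit and property tests for the jellyfish-search operators and the three
full optimizers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jellyfuse.optim import (
    AJSConfig,
    GAConfig,
    JellyfishPopulation,
    OptimizationError,
    PSOConfig,
    SearchSpace,
    active_step,
    ajs_optimize,
    drift_step,
    ga_optimize,
    ocean_current,
    passive_step,
    pso_optimize,
    time_control,
    wrap_bounds,
)

ALL_OPTIMIZERS = [
    (ajs_optimize, AJSConfig),
    (ga_optimize, GAConfig),
    (pso_optimize, PSOConfig),
]


def make_pop(positions, best, costs=None):
    positions = np.asarray(positions, dtype=float)
    costs = np.zeros(len(positions)) if costs is None else np.asarray(costs)
    return JellyfishPopulation(
        positions=positions,
        costs=costs,
        best_position=np.asarray(best, dtype=float),
        best_cost=float(costs.min()),
    )


class TestOperators:
    def test_ocean_current_zero_mean_returns_best(self, fixed_rng):
        pop = make_pop([[1, 1], [-1, -1]], best=[1, 1])
        np.testing.assert_allclose(
            ocean_current(pop, phi=3.0, rng=fixed_rng(0.7)), [1, 1]
        )

    def test_ocean_current_hand_value(self, fixed_rng):
        pop = make_pop([[1, 1], [0, 0]], best=[1, 1])  # column means (0.5, 0.5)
        np.testing.assert_allclose(
            ocean_current(pop, phi=3.0, rng=fixed_rng(0.2)), [0.7, 0.7]
        )

    def test_ocean_current_cancellation(self, fixed_rng):
        # best position equals phi*u*mean exactly -> zero drift vector
        pop = make_pop([[1, 1], [1, 1]], best=[1, 1])
        np.testing.assert_allclose(
            ocean_current(pop, phi=2.0, rng=fixed_rng(0.5)), [0.0, 0.0]
        )

    def test_ocean_current_empty_population_errors(self, fixed_rng):
        pop = JellyfishPopulation(
            positions=np.empty((0, 2)), costs=np.empty(0),
            best_position=np.zeros(2), best_cost=0.0,
        )
        with pytest.raises(OptimizationError):
            ocean_current(pop, phi=3.0, rng=fixed_rng(0.5))

    @pytest.mark.parametrize(
        "position, current, u, expected",
        [
            ([2.0, 3.0], [0.0, 0.0], 0.3, [2.0, 3.0]),
            ([0.0, 0.0], [1.0, 2.0], 0.5, [0.5, 1.0]),
            ([0.0, 0.0], [1.0, 2.0], 1.0, [1.0, 2.0]),
        ],
    )
    def test_drift_step(self, fixed_rng, position, current, u, expected):
        np.testing.assert_allclose(
            drift_step(np.array(position), np.array(current), fixed_rng(u)), expected
        )

    def test_drift_step_length_mismatch(self, fixed_rng):
        with pytest.raises(ValueError):
            drift_step(np.zeros(2), np.zeros(3), fixed_rng(0.5))

    def test_passive_step_hand_value(self, fixed_rng):
        space = SearchSpace.unit(1)
        np.testing.assert_allclose(
            passive_step(np.array([0.5]), space, omega=0.1, rng=fixed_rng(0.5)), [0.55]
        )

    def test_passive_step_zero_omega_is_identity_limit(self, fixed_rng):
        space = SearchSpace.unit(3)
        x = np.array([0.2, 0.5, 0.9])
        out = passive_step(x, space, omega=1e-300, rng=fixed_rng(0.5))
        np.testing.assert_allclose(out, x)

    @pytest.mark.parametrize(
        "ci, cj, expected",
        [
            (5.0, 1.0, [1.0, 0.0]),  # j better: move toward j at u=1
            (1.0, 5.0, [-1.0, 0.0]),  # j worse: move away
            (2.0, 2.0, [1.0, 0.0]),  # tie: toward j
        ],
    )
    def test_active_step_direction(self, fixed_rng, ci, cj, expected):
        out = active_step(np.zeros(2), np.array([1.0, 0.0]), ci, cj, fixed_rng(1.0))
        np.testing.assert_allclose(out, expected)

    def test_active_step_coincident_positions_no_move(self, fixed_rng):
        x = np.array([0.3, 0.4])
        np.testing.assert_allclose(active_step(x, x, 1.0, 2.0, fixed_rng(0.8)), x)

    @pytest.mark.parametrize(
        "t, max_iter, u, expected",
        [
            (50, 50, 0.9, 0.0),  # final iteration: decay factor vanishes
            (10, 50, 0.5, 0.0),  # centred draw: (2u-1) vanishes
            (25, 50, 0.75, 0.25),
        ],
    )
    def test_time_control_values(self, fixed_rng, t, max_iter, u, expected):
        assert time_control(t, max_iter, fixed_rng(u)) == pytest.approx(expected)

    def test_time_control_rejects_out_of_range_t(self, fixed_rng):
        with pytest.raises(ValueError):
            time_control(0, 50, fixed_rng(0.5))
        with pytest.raises(ValueError):
            time_control(51, 50, fixed_rng(0.5))

    @given(t=st.integers(1, 50), u=st.floats(0.0, 1.0))
    @settings(deadline=None)
    def test_time_control_range_property(self, t, u):
        from conftest import FixedRng

        val = time_control(t, 50, FixedRng(u))
        assert 0.0 <= val < 1.0
        if t == 50:
            assert val == 0.0

    @pytest.mark.parametrize(
        "x, expected",
        [(0.5, 0.5), (1.2, 0.2), (-0.3, 0.7), (2.4, 0.4), (-1.6, 0.4)],
    )
    def test_wrap_bounds_unit_interval(self, x, expected):
        space = SearchSpace.unit(1)
        assert wrap_bounds(np.array([x]), space)[0] == pytest.approx(expected)

    def test_wrap_bounds_nonfinite_errors(self):
        with pytest.raises(OptimizationError):
            wrap_bounds(np.array([np.nan]), SearchSpace.unit(1))

    @given(x=st.floats(-50, 50), lo=st.floats(-2, 0), hi=st.floats(0.5, 3))
    @settings(deadline=None)
    def test_wrap_bounds_always_feasible(self, x, lo, hi):
        space = SearchSpace(1, np.array([lo]), np.array([hi]))
        out = wrap_bounds(np.array([x]), space)
        assert lo <= out[0] <= hi


class TestSearchSpace:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(2, np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_rejects_wrong_lengths(self):
        with pytest.raises(ValueError):
            SearchSpace(3, np.zeros(2), np.ones(2))


class TestFullOptimizers:
    @pytest.mark.parametrize("optimize, config_cls", ALL_OPTIMIZERS)
    def test_constant_objective_flat_trace(self, optimize, config_cls):
        res = optimize(lambda x: 7.5, SearchSpace.unit(2), config_cls(seed=3))
        assert res.best_cost == 7.5
        assert np.all(res.trace == 7.5)

    @pytest.mark.parametrize("optimize, config_cls", ALL_OPTIMIZERS)
    def test_trace_monotone_and_consistent(self, optimize, config_cls):
        res = optimize(
            lambda x: float((x**2).sum()), SearchSpace.cube(3, -1, 1), config_cls(seed=5)
        )
        assert np.all(np.diff(res.trace) <= 0)
        assert res.trace[-1] == res.best_cost
        assert len(res.trace) == 51  # initialization + 50 iterations

    @pytest.mark.parametrize("optimize, config_cls", ALL_OPTIMIZERS)
    def test_seed_reproducibility(self, optimize, config_cls):
        f = lambda x: float((x**2).sum())
        space = SearchSpace.cube(2, -1, 1)
        a = optimize(f, space, config_cls(seed=11))
        b = optimize(f, space, config_cls(seed=11))
        assert np.array_equal(a.best_position, b.best_position)
        assert np.array_equal(a.trace, b.trace)

    @pytest.mark.parametrize("optimize, config_cls", ALL_OPTIMIZERS)
    def test_quadratic_close_to_grid_optimum(self, optimize, config_cls):
        """All three optimizers land near the brute-force grid optimum of a
        1-D quadratic (grid step 1e-4 places it at x=0.25)."""
        grid = np.arange(0, 1 + 1e-4, 1e-4)
        grid_opt = grid[np.argmin((grid - 0.25) ** 2)]
        hits = 0
        for seed in range(5):
            res = optimize(
                lambda x: float((x[0] - 0.25) ** 2),
                SearchSpace.unit(1),
                config_cls(seed=seed),
            )
            hits += abs(res.best_position[0] - grid_opt) < 0.05
        assert hits >= 4

    def test_ga_better_than_initial_population(self):
        # elitism guarantees the final best is no worse than the first
        f = lambda x: float((x**2).sum())
        res = ga_optimize(f, SearchSpace.cube(3, -1, 1), GAConfig(seed=2))
        assert res.best_cost <= res.trace[0]

    def test_pso_stationary_at_optimum(self):
        # all particles at the optimum with zero velocity stay put
        space = SearchSpace.cube(2, -1, 1)
        calls = []

        def f(x):
            calls.append(x.copy())
            return float((x**2).sum())

        res = pso_optimize(f, space, PSOConfig(pop_size=2, max_iter=3, seed=0))
        assert np.all(np.diff(res.trace) <= 0)

    def test_nonfinite_objective_aborts(self):
        with pytest.raises(OptimizationError):
            ajs_optimize(lambda x: float("nan"), SearchSpace.unit(2), AJSConfig(seed=0))

    def test_ajs_positions_stay_in_bounds(self):
        space = SearchSpace.cube(3, -2, 2)
        seen = []

        def f(x):
            seen.append(x.copy())
            return float((x**2).sum())

        ajs_optimize(f, space, AJSConfig(seed=9, max_iter=20))
        assert all(space.contains(x) for x in seen)


class TestConfigValidation:
    def test_ajs_config_rejects_bad_values(self):
        with pytest.raises(ValueError):
            AJSConfig(pop_size=1)
        with pytest.raises(ValueError):
            AJSConfig(phi=0)
        with pytest.raises(ValueError):
            AJSConfig(c0=1.0)
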