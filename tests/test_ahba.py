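import numpy as np
import pytest

from mitoboost import ahba
from mitoboost.ahba import (
    AHBAConfig,
    InvalidConfigError,
    InvalidSpaceError,
    Population,
    SearchSpace,
    guided_foraging_step,
    init_visit_table,
    initialize_population,
    migration_step,
    optimize,
    sample_flight_direction,
    territorial_foraging_step,
    update_visit_table,
)

sphere = lambda x: float(np.sum(np.asarray(x) ** 2))


class FixedUniformRNG:
    """Stub returning a constant for uniform draws (initialization tests)."""

    def __init__(self, value):
        self.value = value

    def uniform(self, size=None):
        return np.full(size, self.value) if size is not None else self.value


class TestSearchSpace:
    def test_crossed_bounds_rejected(self):
        with pytest.raises(InvalidSpaceError):
            SearchSpace(np.array([0.0, 2.0]), np.array([1.0, 1.0]))

    def test_clamp(self):
        space = SearchSpace(np.zeros(2), np.ones(2))
        assert np.allclose(space.clamp(np.array([-1.0, 2.0])), [0.0, 1.0])


class TestInitializePopulation:
    def test_degenerate_bounds_collapse_to_point(self, rng):
        space = SearchSpace(np.array([3.0, 3.0]), np.array([3.0, 3.0]))
        pop = initialize_population(space, 5, sphere, rng)
        assert np.all(pop.positions == 3.0)

    def test_fixed_half_draw_lands_at_midpoint(self):
        space = SearchSpace(np.zeros(2), np.ones(2))
        pop = initialize_population(space, 2, sphere, FixedUniformRNG(0.5))
        assert np.allclose(pop.positions, 0.5)

    def test_positions_within_bounds_and_fitness_evaluated(self, rng):
        space = SearchSpace(np.full(5, -2.0), np.full(5, 7.0))
        pop = initialize_population(space, 10, sphere, rng)
        assert pop.positions.shape == (10, 5)
        assert np.all(pop.positions >= -2.0) and np.all(pop.positions <= 7.0)
        assert np.allclose(pop.fitness, [sphere(x) for x in pop.positions])

    def test_population_too_small_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            initialize_population(SearchSpace(np.zeros(1), np.ones(1)), 1, sphere, rng)


class TestVisitTable:
    def test_init_shape_nulls_and_zeros(self):
        vt = init_visit_table(3)
        assert vt.shape == (3, 3)
        assert vt[0, 1] == 0 and vt[1, 0] == 0
        assert np.isnan(np.diag(vt)).all()
        assert np.sum(np.isnan(vt)) == 3

    @pytest.mark.parametrize("n", [2, 6])
    def test_null_count_equals_n(self, n):
        assert np.sum(np.isnan(init_visit_table(n))) == n

    def test_too_small_rejected(self):
        with pytest.raises(InvalidConfigError):
            init_visit_table(1)

    def test_single_visit_bookkeeping(self):
        vt = init_visit_table(3)
        update_visit_table(vt, 0, 1)
        assert np.isnan(vt[0, 0])
        assert vt[0, 1] == 0 and vt[0, 2] == 1

    def test_repeat_visits_keep_target_fresh_while_others_age(self):
        vt = init_visit_table(3)
        update_visit_table(vt, 0, 1)
        update_visit_table(vt, 0, 1)
        assert vt[0, 1] == 0 and vt[0, 2] == 2

    def test_replaced_source_jumps_above_row_maximum(self):
        vt = init_visit_table(3)
        update_visit_table(vt, 0, 1)
        update_visit_table(vt, 0, 1, replaced_source=0)
        # birds 1 and 2 have never seen source 0's new position
        assert vt[1, 0] == np.nanmax(vt[1]) and vt[2, 0] == np.nanmax(vt[2])

    def test_self_visit_rejected(self):
        with pytest.raises(ValueError):
            update_visit_table(init_visit_table(3), 1, 1)

    def test_diagonal_stays_null_after_updates(self, rng):
        vt = init_visit_table(4)
        for _ in range(20):
            i = int(rng.integers(4))
            j = int((i + 1 + rng.integers(3)) % 4)
            if i != j:
                update_visit_table(vt, i, j)
        assert np.isnan(np.diag(vt)).all()


class TestFlightDirections:
    def test_omnidirectional_activates_all(self, rng):
        assert np.all(sample_flight_direction("omnidirectional", 4, rng) == 1)

    def test_axial_activates_exactly_one(self, rng):
        for _ in range(50):
            assert sample_flight_direction("axial", 5, rng).sum() == 1

    def test_diagonal_active_count_bounds(self, rng):
        # with r1=0.5, d=10 the active count must land in [2, ceil(0.5*8)+1] = [2,5]
        for _ in range(200):
            k = sample_flight_direction("diagonal", 10, rng, r1=0.5).sum()
            assert 2 <= k <= 5

    def test_diagonal_low_dimension_falls_back_to_axial(self, rng):
        assert sample_flight_direction("diagonal", 2, rng).sum() == 1

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            sample_flight_direction("sideways", 3, rng)

    def test_combinatorics_over_many_draws(self, rng):
        d = 8
        for _ in range(2000):
            assert sample_flight_direction("axial", d, rng).sum() == 1
            r1 = float(rng.uniform())
            k = sample_flight_direction("diagonal", d, rng, r1=r1).sum()
            assert 2 <= k <= np.ceil(r1 * (d - 2)) + 1
            assert sample_flight_direction("omnidirectional", d, rng).sum() == d


def _two_bird_state(positions, objective):
    positions = np.array(positions, dtype=float)
    pop = Population(positions=positions.copy(),
                     fitness=np.array([objective(x) for x in positions]))
    return pop, init_visit_table(len(positions))


class TestForagingSteps:
    def test_guided_zero_step_lands_on_target(self, rng):
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        pop, vt = _two_bird_state([(0.0, 0.0), (2.0, 2.0)], sphere)
        guided_foraging_step(pop, vt, 1, sphere, space, rng, a=0.0)
        assert np.allclose(pop.positions[1], [0.0, 0.0])  # candidate == target, better

    def test_guided_hand_evaluated_candidate(self, rng):
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        pop, vt = _two_bird_state([(0.0, 0.0), (2.0, 2.0)], sphere)
        guided_foraging_step(pop, vt, 1, sphere, space, rng,
                             a=1.0, D=np.array([1.0, 0.0]))
        # v = target + a*D*(x_i - target) = (2, 0), which improves on (2,2)
        assert np.allclose(pop.positions[1], [2.0, 0.0])

    def test_guided_worse_candidate_leaves_bird_unchanged(self, rng):
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        pop, vt = _two_bird_state([(5.0, 5.0), (0.1, 0.1)], sphere)
        guided_foraging_step(pop, vt, 1, sphere, space, rng,
                             a=-1.0, D=np.ones(2))  # v = 2*target - x_i, far worse
        assert np.allclose(pop.positions[1], [0.1, 0.1])

    def test_territorial_zero_step_is_a_no_op(self, rng):
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        pop, vt = _two_bird_state([(1.0, 1.0), (3.0, 3.0)], sphere)
        territorial_foraging_step(pop, vt, 0, sphere, space, rng, b=0.0)
        assert np.allclose(pop.positions[0], [1.0, 1.0])

    def test_territorial_hand_evaluated_candidate(self, rng):
        objective = lambda x: -float(np.sum(x))  # pushes outward
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        pop, vt = _two_bird_state([(1.0, 1.0), (5.0, 5.0)], objective)
        territorial_foraging_step(pop, vt, 0, objective, space, rng,
                                  b=1.0, D=np.ones(2))
        assert np.allclose(pop.positions[0], [2.0, 2.0])  # v = x + b*D*x

    def test_territorial_candidate_clamped_to_bounds(self, rng):
        objective = lambda x: -float(np.sum(x))
        space = SearchSpace(np.full(2, -10.0), np.full(2, 1.5))
        pop, vt = _two_bird_state([(1.0, 1.0), (0.0, 0.0)], objective)
        territorial_foraging_step(pop, vt, 0, objective, space, rng,
                                  b=1.0, D=np.ones(2))
        assert np.allclose(pop.positions[0], [1.5, 1.5])


class TestMigration:
    def test_worst_replaced_in_bounds_best_untouched(self, rng):
        space = SearchSpace(np.full(3, -4.0), np.full(3, 4.0))
        pop = initialize_population(space, 6, sphere, rng)
        vt = init_visit_table(6)
        best = pop.best_index
        best_pos = pop.positions[best].copy()
        w = migration_step(pop, vt, sphere, space, rng)
        assert w != best
        assert np.allclose(pop.positions[best], best_pos)
        assert np.all(pop.positions[w] >= -4.0) and np.all(pop.positions[w] <= 4.0)

    def test_degenerate_bounds_replacement_is_identity(self, rng):
        space = SearchSpace(np.full(2, 1.0), np.full(2, 1.0))
        pop = initialize_population(space, 3, sphere, rng)
        vt = init_visit_table(3)
        migration_step(pop, vt, sphere, space, rng)
        assert np.all(pop.positions == 1.0)


class TestOptimize:
    def test_constant_objective_trace_is_flat(self):
        space = SearchSpace(np.zeros(3), np.ones(3))
        res = optimize(lambda x: 7.0, space, AHBAConfig(n=4, max_iters=30, seed=0))
        assert np.all(res.trace == 7.0)

    def test_trace_non_increasing_and_positions_in_bounds(self):
        space = SearchSpace(np.full(4, -3.0), np.full(4, 3.0))
        for seed in range(3):
            res = optimize(sphere, space, AHBAConfig(n=8, max_iters=50, seed=seed))
            assert np.all(np.diff(res.trace) <= 0)
            assert np.all(res.x >= -3.0) and np.all(res.x <= 3.0)

    def test_identical_seeds_identical_traces(self):
        space = SearchSpace(np.full(3, -5.0), np.full(3, 5.0))
        cfg = AHBAConfig(n=6, max_iters=40, seed=99)
        r1 = optimize(sphere, space, cfg)
        r2 = optimize(sphere, space, cfg)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.array_equal(r1.x, r2.x)

    def test_non_finite_objective_names_position(self):
        space = SearchSpace(np.zeros(2), np.ones(2))
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: float("nan"), space, AHBAConfig(n=3, max_iters=5, seed=0))

    def test_beats_random_search_on_sphere(self):
        # same total evaluation budget, 10 seeds, 2-D sphere
        space = SearchSpace(np.full(2, -5.0), np.full(2, 5.0))
        aha_finals, rs_finals = [], []
        for seed in range(10):
            res = optimize(sphere, space, AHBAConfig(n=20, max_iters=500, seed=seed))
            aha_finals.append(res.fun)
            rs = ahba.random_search(sphere, space, res.n_evals, seed=seed)
            rs_finals.append(rs.fun)
        assert np.median(aha_finals) < np.median(rs_finals)
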