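import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventinv import gpso


def sphere(x):
    return np.sum(np.asarray(x) ** 2, axis=-1)


def tied_social_sampler(rng, n, d):
    """Scalar draws with r3 tied to r2, for the classic-PSO reduction."""
    r1 = rng.uniform(size=(n, 1))
    r2 = rng.uniform(size=(n, 1))
    return r1, r2, r2


def classic_sampler(rng, n, d):
    r1 = rng.uniform(size=(n, 1))
    r2 = rng.uniform(size=(n, 1))
    return r1, r2


class TestBounds:
    def test_validation(self):
        with pytest.raises(ValueError):
            gpso.Bounds([1.0, 0.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            gpso.Bounds([0.0], [0.0, 1.0])

    def test_degenerate_allowed(self):
        b = gpso.Bounds([2.0, 2.0], [2.0, 2.0])
        assert b.contains([2.0, 2.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=6),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_clamp_always_inside(self, lows, seed):
        rng = np.random.default_rng(seed)
        lo = np.asarray(lows)
        b = gpso.Bounds(lo, lo + rng.uniform(0, 10, size=lo.size))
        x = rng.normal(scale=200, size=(5, lo.size))
        assert b.contains(b.clamp(x))


class TestConfig:
    def test_defaults_are_full_scale(self):
        cfg = gpso.GPSOConfig()
        assert cfg.population == 2000
        assert cfg.n_groups == 50
        assert cfg.omega == 0.8
        assert cfg.c1 == cfg.c2 == cfg.c3 == 1.2

    def test_profiles(self):
        t2 = gpso.GPSOConfig.from_profile("table2")
        assert (t2.max_iterations, t2.fitness_tolerance) == (100, 1e-2)
        tx = gpso.GPSOConfig.from_profile("text")
        assert (tx.max_iterations, tx.fitness_tolerance) == (1000, 1e-4)

    def test_indivisible_population_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            gpso.GPSOConfig(population=10, n_groups=3)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            gpso.GPSOConfig(population=0, n_groups=1)
        with pytest.raises(ValueError):
            gpso.GPSOConfig(max_iterations=0)
        with pytest.raises(ValueError):
            gpso.GPSOConfig(omega=1.5)


class TestInitializeSwarm:
    def test_construction_contract(self):
        cfg = gpso.GPSOConfig(population=4, n_groups=2, seed=1)
        bounds = gpso.Bounds([0.0, 0.0], [1.0, 1.0])
        swarm, groups = gpso.initialize_swarm(cfg, bounds, sphere, vectorized=True)
        assert swarm.position.shape == (4, 2)
        assert np.array_equal(groups.membership, [0, 0, 1, 1])
        assert bounds.contains(swarm.position)
        assert np.all(swarm.velocity == 0.0)
        assert np.array_equal(swarm.pbest, swarm.position)

    def test_degenerate_bounds_collapse(self):
        cfg = gpso.GPSOConfig(population=6, n_groups=3, seed=0)
        bounds = gpso.Bounds([3.0, -1.0], [3.0, -1.0])
        swarm, groups = gpso.initialize_swarm(cfg, bounds, sphere, vectorized=True)
        assert np.all(swarm.position == [3.0, -1.0])
        assert np.array_equal(groups.universal_best, [3.0, -1.0])

    def test_full_scale_partition(self):
        cfg = gpso.GPSOConfig(population=2000, n_groups=50, seed=0)
        bounds = gpso.Bounds([0.0], [1.0])
        swarm, groups = gpso.initialize_swarm(cfg, bounds, sphere, vectorized=True)
        counts = np.bincount(groups.membership)
        assert counts.size == 50
        assert np.all(counts == 40)


class TestUpdateVelocity:
    def _one_particle(self, x, v, pbest, gbest, ubest):
        swarm = gpso.Swarm(
            position=np.array([[float(x)]]),
            velocity=np.array([[float(v)]]),
            pbest=np.array([[float(pbest)]]),
            pbest_fitness=np.array([0.0]),
        )
        groups = gpso.GroupStructure(
            n_groups=1,
            membership=np.array([0]),
            group_best=np.array([[float(gbest)]]),
            group_best_fitness=np.array([0.0]),
            universal_best=np.array([float(ubest)]),
            universal_best_fitness=0.0,
        )
        return swarm, groups

    def test_all_difference_terms_vanish(self):
        swarm, groups = self._one_particle(x=2.0, v=0.0, pbest=2.0, gbest=2.0, ubest=2.0)
        cfg = gpso.GPSOConfig(population=1, n_groups=1)
        v = gpso.update_velocity(swarm, groups, cfg, np.random.default_rng(0))
        assert np.all(v == 0.0)

    def test_hand_computed_update(self):
        # w=0.8, c=1.2, forced r=1, v=0, x=0, pbest=1, gbest=2, ubest=3
        # -> v' = 1.2*1 + 1.2*2 + 1.2*3 = 7.2
        swarm, groups = self._one_particle(x=0.0, v=0.0, pbest=1.0, gbest=2.0, ubest=3.0)
        cfg = gpso.GPSOConfig(population=1, n_groups=1, omega=0.8, c1=1.2, c2=1.2, c3=1.2)
        ones = lambda rng, n, d: (np.ones((n, 1)),) * 3
        v = gpso.update_velocity(swarm, groups, cfg, np.random.default_rng(0), r_sampler=ones)
        assert v[0, 0] == pytest.approx(7.2, abs=1e-12)

    def test_single_group_merges_social_terms(self):
        # one group: gbest == ubest, tied draws act like classic PSO with c2 + c3
        swarm, groups = self._one_particle(x=0.0, v=0.0, pbest=0.0, gbest=2.0, ubest=2.0)
        cfg = gpso.GPSOConfig(population=1, n_groups=1, omega=0.0, c1=0.0, c2=1.2, c3=1.2)
        half = lambda rng, n, d: (np.full((n, 1), 0.5),) * 3
        v = gpso.update_velocity(swarm, groups, cfg, np.random.default_rng(0), r_sampler=half)
        # classic PSO with c2' = 2.4, r = 0.5: v = 0.5 * 2.4 * (2 - 0) = 2.4
        assert v[0, 0] == pytest.approx(2.4, abs=1e-12)


class TestUpdatePosition:
    def test_clamped_to_upper(self):
        swarm = gpso.Swarm(
            position=np.array([[0.9]]), velocity=np.array([[0.3]]),
            pbest=np.array([[0.9]]), pbest_fitness=np.array([0.0]),
        )
        assert gpso.update_position(swarm, gpso.Bounds([0.0], [1.0]))[0, 0] == 1.0

    def test_plain_arithmetic(self):
        swarm = gpso.Swarm(
            position=np.array([[0.2]]), velocity=np.array([[0.3]]),
            pbest=np.array([[0.2]]), pbest_fitness=np.array([0.0]),
        )
        assert gpso.update_position(swarm, gpso.Bounds([0.0], [1.0]))[0, 0] == pytest.approx(0.5)


class TestLeaders:
    def test_single_particle_degenerate(self):
        cfg = gpso.GPSOConfig(population=1, n_groups=1, max_iterations=5,
                              fitness_tolerance=0.0, seed=4)
        bounds = gpso.Bounds([-1.0], [1.0])
        trace = gpso.optimize(sphere, bounds, cfg, vectorized=True)
        assert trace.final_best_fitness == pytest.approx(trace.final_pbest_fitness[0])

    def test_universal_best_dominates_group_bests(self):
        cfg = gpso.GPSOConfig(population=20, n_groups=4, seed=9)
        bounds = gpso.Bounds([-5.0] * 3, [5.0] * 3)
        swarm, groups = gpso.initialize_swarm(cfg, bounds, sphere, vectorized=True)
        for _ in range(10):
            rng = np.random.default_rng(0)
            swarm.velocity = gpso.update_velocity(swarm, groups, cfg, rng)
            swarm.position = gpso.update_position(swarm, bounds)
            f = sphere(swarm.position)
            gpso.update_leaders(swarm, groups, f)
            assert groups.universal_best_fitness <= groups.group_best_fitness.min()
            for j in range(groups.n_groups):
                members = groups.membership == j
                assert groups.group_best_fitness[j] <= swarm.pbest_fitness[members].min() + 1e-15

    def test_pbest_fitness_monotone_over_run(self):
        cfg = gpso.GPSOConfig(population=12, n_groups=3, max_iterations=30,
                              fitness_tolerance=0.0, seed=11)
        bounds = gpso.Bounds([-5.0] * 2, [5.0] * 2)
        swarm, groups = gpso.initialize_swarm(
            cfg, bounds, sphere, rng=np.random.default_rng(11), vectorized=True
        )
        rng = np.random.default_rng(12)
        prev = swarm.pbest_fitness.copy()
        for _ in range(30):
            swarm.velocity = gpso.update_velocity(swarm, groups, cfg, rng)
            swarm.position = gpso.update_position(swarm, bounds)
            gpso.update_leaders(swarm, groups, sphere(swarm.position))
            assert np.all(swarm.pbest_fitness <= prev + 1e-15)
            prev = swarm.pbest_fitness.copy()

    def test_non_finite_fitness_treated_as_inf(self, caplog):
        def nasty(x):
            f = np.sum(x**2, axis=1)
            f[x[:, 0] > 0] = np.nan
            return f

        cfg = gpso.GPSOConfig(population=30, n_groups=3, max_iterations=20,
                              fitness_tolerance=0.0, seed=2)
        trace = gpso.optimize(nasty, gpso.Bounds([-1.0] * 2, [1.0] * 2), cfg, vectorized=True)
        assert np.isfinite(trace.final_best_fitness)
        assert trace.final_best_position[0] <= 0


class TestOptimize:
    def test_sphere_benchmark_deep(self):
        cfg = gpso.GPSOConfig(population=200, n_groups=10, max_iterations=1000,
                              fitness_tolerance=1e-12, seed=0)
        bounds = gpso.Bounds([-5.0] * 8, [5.0] * 8)
        trace = gpso.optimize(sphere, bounds, cfg, vectorized=True)
        assert trace.final_best_fitness < 1e-6

    def test_constant_objective(self):
        cfg = gpso.GPSOConfig(population=10, n_groups=2, max_iterations=15,
                              fitness_tolerance=0.0, seed=0)
        trace = gpso.optimize(lambda x: np.full(x.shape[0], 3.5),
                              gpso.Bounds([0.0], [1.0]), cfg, vectorized=True)
        assert np.all(trace.best_fitness_per_iteration == 3.5)
        assert trace.terminated_by == "iteration_cap"
        assert trace.iterations_used == 15

    def test_monotone_best_fitness(self):
        cfg = gpso.GPSOConfig(population=40, n_groups=4, max_iterations=100,
                              fitness_tolerance=0.0, seed=5)
        trace = gpso.optimize(sphere, gpso.Bounds([-5.0] * 4, [5.0] * 4), cfg, vectorized=True)
        diffs = np.diff(trace.best_fitness_per_iteration)
        assert np.all(diffs <= 0)

    def test_feasibility_full_trace(self):
        cfg = gpso.GPSOConfig(population=30, n_groups=3, max_iterations=50,
                              fitness_tolerance=0.0, seed=3)
        bounds = gpso.Bounds([-2.0, 0.0, 5.0], [2.0, 1.0, 9.0])
        trace = gpso.optimize(sphere, bounds, cfg, vectorized=True,
                              fixed_dims={2: 6.5}, record_positions=True)
        for snapshot in trace.positions_history:
            assert bounds.contains(snapshot)
            assert np.all(snapshot[:, 2] == 6.5)
        assert trace.final_best_position[2] == 6.5

    def test_tolerance_termination(self):
        cfg = gpso.GPSOConfig(population=100, n_groups=10, max_iterations=1000,
                              fitness_tolerance=1e-3, seed=0)
        trace = gpso.optimize(sphere, gpso.Bounds([-5.0] * 2, [5.0] * 2), cfg, vectorized=True)
        assert trace.terminated_by == "tolerance"
        assert trace.final_best_fitness < 1e-3
        assert trace.iterations_used < 1000

    def test_reproducibility(self):
        cfg = gpso.GPSOConfig(population=40, n_groups=4, max_iterations=60,
                              fitness_tolerance=0.0, seed=77)
        bounds = gpso.Bounds([-5.0] * 4, [5.0] * 4)
        a = gpso.optimize(sphere, bounds, cfg, vectorized=True)
        b = gpso.optimize(sphere, bounds, cfg, vectorized=True)
        assert np.array_equal(a.best_fitness_per_iteration, b.best_fitness_per_iteration)
        assert np.array_equal(a.final_best_position, b.final_best_position)

    def test_scalar_objective_supported(self):
        cfg = gpso.GPSOConfig(population=10, n_groups=2, max_iterations=10,
                              fitness_tolerance=0.0, seed=1)
        trace = gpso.optimize(lambda x: float(np.sum(x**2)),
                              gpso.Bounds([-1.0] * 2, [1.0] * 2), cfg)
        assert np.isfinite(trace.final_best_fitness)


class TestClassicReduction:
    def test_single_group_equals_classic_pso_bit_for_bit(self):
        bounds = gpso.Bounds([-5.0] * 8, [5.0] * 8)
        graded = gpso.GPSOConfig(population=60, n_groups=1, omega=0.8,
                                 c1=1.2, c2=1.2, c3=1.2, max_iterations=100,
                                 fitness_tolerance=0.0, seed=13)
        classic = gpso.GPSOConfig(population=60, n_groups=1, omega=0.8,
                                  c1=1.2, c2=2.4, c3=0.0, max_iterations=100,
                                  fitness_tolerance=0.0, seed=13)
        tg = gpso.optimize(sphere, bounds, graded, vectorized=True,
                           r_sampler=tied_social_sampler, record_positions=True)
        tp = gpso.pso_optimize(sphere, bounds, classic, vectorized=True,
                               r_sampler=classic_sampler, record_positions=True)
        assert len(tg.positions_history) == len(tp.positions_history)
        for a, b in zip(tg.positions_history, tp.positions_history):
            assert np.array_equal(a, b)
        assert np.array_equal(tg.best_fitness_per_iteration, tp.best_fitness_per_iteration)

    def test_singleton_groups_also_reduce(self):
        # one member per group: every group best is the member's own pbest
        bounds = gpso.Bounds([-5.0] * 4, [5.0] * 4)
        cfg = gpso.GPSOConfig(population=16, n_groups=16, omega=0.8,
                              c1=1.2, c2=1.2, c3=1.2, max_iterations=40,
                              fitness_tolerance=0.0, seed=21)
        swarm, groups = gpso.initialize_swarm(
            cfg, bounds, sphere, rng=np.random.default_rng(21), vectorized=True
        )
        assert np.array_equal(groups.group_best, swarm.pbest)


class TestClassicPSO:
    def test_single_term_update_moves_toward_gbest(self):
        cfg = gpso.GPSOConfig(population=20, n_groups=1, omega=0.0, c1=0.0,
                              c2=0.9, c3=0.0, max_iterations=1,
                              fitness_tolerance=0.0, seed=8)
        bounds = gpso.Bounds([-5.0] * 2, [5.0] * 2)
        trace = gpso.pso_optimize(sphere, bounds, cfg, vectorized=True, record_positions=True)
        before, after = trace.positions_history[0], trace.positions_history[1]
        gbest_before = before[np.argmin(sphere(before))]
        step = after - before
        toward = gbest_before - before
        moving = np.abs(toward) > 1e-12
        assert np.all(np.sign(step[moving]) == np.sign(toward[moving]))

    def test_2d_sphere_benchmark(self):
        cfg = gpso.GPSOConfig(population=50, n_groups=1, max_iterations=500,
                              fitness_tolerance=0.0, seed=0)
        trace = gpso.pso_optimize(sphere, gpso.Bounds([-5.0] * 2, [5.0] * 2),
                                  cfg, vectorized=True)
        assert trace.final_best_fitness < 1e-4


def test_statistical_convergence_desk_scale():
    bounds = gpso.Bounds([-5.0] * 8, [5.0] * 8)
    reached = 0
    for seed in range(20):
        cfg = gpso.GPSOConfig(population=200, n_groups=10, max_iterations=1000,
                              fitness_tolerance=1e-4, seed=seed)
        trace = gpso.optimize(sphere, bounds, cfg, vectorized=True)
        reached += trace.final_best_fitness < 1e-4
    assert reached >= 19
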