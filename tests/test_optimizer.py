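"""Swarm engine: chaos map, updates, immune operators, bound adaptation, inversion."""

import numpy as np
import pytest

from mese_relaxo.acquisition import simulate_decay
from mese_relaxo.optimizer import (
    ComponentBounds,
    OptimizerConfig,
    SwarmState,
    adapt_bounds,
    chaos_step,
    default_bounds,
    immune_operators,
    invert,
    pso_update,
    _make_fitness,
)
from mese_relaxo.relaxometry import DecayCurve, loglinear_mono_fit


class TestChaosStep:
    def test_logistic_arithmetic(self):
        assert chaos_step(0.25) == pytest.approx(0.75)
        assert chaos_step(0.5) == pytest.approx(1.0)
        assert chaos_step(0.3) == pytest.approx(4 * 0.3 * 0.7)

    def test_absorbing_values_reseeded(self):
        rng = np.random.default_rng(0)
        for bad in (0.0, 1.0, -0.2, 1.5, 0.75):
            out = chaos_step(bad, rng)
            assert 0.0 <= out <= 1.0
            # a reseeded orbit keeps moving
            assert chaos_step(out, rng) != out

    def test_long_orbit_contained_and_nondegenerate(self):
        # 1e4 iterates from 0.3 stay in [0,1] with nontrivial variance
        rng = np.random.default_rng(1)
        r = 0.3
        orbit = []
        for _ in range(10_000):
            r = chaos_step(r, rng)
            orbit.append(r)
        orbit = np.asarray(orbit)
        assert orbit.min() >= 0.0 and orbit.max() <= 1.0
        assert orbit.var() > 0.05


class TestPsoUpdate:
    def setup_method(self):
        self.bounds = ComponentBounds(np.array([0.0, 1.0]), np.array([10.0, 100.0]))

    def test_degenerate_coefficients_pure_inertia(self):
        x = np.array([5.0, 50.0])
        v = np.array([0.5, -1.0])
        x2, v2 = pso_update(x, v, x, x, w=1.0, c1=0.0, c2=0.0, r1=0.5, r2=0.5, bounds=self.bounds)
        np.testing.assert_allclose(v2, v)
        np.testing.assert_allclose(x2, x + v)

    def test_attraction_vanishes_at_bests(self):
        x = np.array([5.0, 50.0])
        v = np.array([1.0, 2.0])
        x2, v2 = pso_update(x, v, x, x, w=0.7, c1=2.0, c2=2.0, r1=0.9, r2=0.9, bounds=self.bounds)
        np.testing.assert_allclose(v2, 0.7 * v)

    def test_positions_stay_in_bounds_over_many_updates(self, rng):
        # single particle on a 1-D-style quadratic: clipping keeps x in bounds
        x = np.array([5.0, 50.0])
        v = np.array([0.0, 0.0])
        pbest = np.array([9.0, 90.0])
        gbest = np.array([1.0, 10.0])
        for _ in range(1000):
            r1, r2 = rng.random(), rng.random()
            x, v = pso_update(x, v, pbest, gbest, 0.7, 2.0, 2.0, r1, r2, self.bounds)
            assert self.bounds.contains(x)

    def test_clipped_dimensions_get_zero_velocity(self):
        x = np.array([9.9, 50.0])
        v = np.array([5.0, 0.0])
        x2, v2 = pso_update(x, v, x, x, 1.0, 0.0, 0.0, 0.5, 0.5, self.bounds)
        assert x2[0] == 10.0 and v2[0] == 0.0


def _make_swarm(fitness_fn, bounds, n=8, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(bounds.lower, bounds.upper, (n, bounds.lower.size))
    f = fitness_fn(x)
    k = int(np.argmin(f))
    return SwarmState(
        x=x, v=np.zeros_like(x), fitness=f, pbest_x=x.copy(), pbest_f=f.copy(),
        gbest_x=x[k].copy(), gbest_f=float(f[k]), r1=0.3, r2=0.6,
    ), rng


class TestImmuneOperators:
    bounds = ComponentBounds(np.array([0.0, 1.0]), np.array([10.0, 100.0]))

    @staticmethod
    def fitness(x):
        x = np.atleast_2d(x)
        return np.sum((x - np.array([3.0, 30.0])) ** 2, axis=1)

    def test_noop_configuration_leaves_swarm_unchanged(self):
        swarm, rng = _make_swarm(self.fitness, self.bounds)
        cfg = OptimizerConfig(n_particles=8, clone_count=0, mutation_prob=0.0, crossover_prob=0.0)
        out = immune_operators(swarm, cfg, self.fitness, self.bounds, rng)
        np.testing.assert_array_equal(out.x, swarm.x)

    def test_elitist_selection_never_worsens(self):
        swarm, rng = _make_swarm(self.fitness, self.bounds)
        cfg = OptimizerConfig(n_particles=8, clone_count=3, seed=0)
        out = immune_operators(swarm, cfg, self.fitness, self.bounds, rng)
        assert out.x.shape == swarm.x.shape
        assert out.fitness.min() <= swarm.fitness.min()
        assert out.gbest_f <= swarm.gbest_f

    def test_survivors_respect_bounds(self):
        swarm, rng = _make_swarm(self.fitness, self.bounds, seed=5)
        cfg = OptimizerConfig(n_particles=8, clone_count=3, mutation_prob=0.8, seed=5)
        out = immune_operators(swarm, cfg, self.fitness, self.bounds, rng)
        assert np.all(out.x >= self.bounds.lower) and np.all(out.x <= self.bounds.upper)


class TestAdaptBounds:
    def test_centered_incumbent_no_update(self):
        b = ComponentBounds(np.array([0.0, 1.0]), np.array([10.0, 101.0]), s=0.6)
        out = adapt_bounds(b, np.array([5.0, 51.0]))
        np.testing.assert_array_equal(out.lower, b.lower)
        np.testing.assert_array_equal(out.upper, b.upper)

    def test_far_upper_bound_compresses(self):
        # incumbent near the lower edge: m1 in (s, 1) -> upper moves down
        b = ComponentBounds(np.array([0.0, 1.0]), np.array([10.0, 101.0]), s=0.6, gamma=5.0)
        out = adapt_bounds(b, np.array([2.0, 11.0]))
        assert out.upper[0] < b.upper[0]
        assert out.upper[1] < b.upper[1]
        assert np.all(out.lower == b.lower)  # m2 = 0.2 < s: no lower move

    def test_incumbent_on_bound_leaves_dimension_unchanged(self):
        b = ComponentBounds(np.array([0.0, 1.0]), np.array([10.0, 101.0]))
        out = adapt_bounds(b, np.array([0.0, 50.0]))
        assert out.lower[0] == 0.0 and out.upper[0] == 10.0

    def test_iterated_adaptation_monotone_and_keeps_incumbent(self):
        b = ComponentBounds(np.array([0.0, 1.0]), np.array([10.0, 101.0]))
        star = np.array([2.0, 80.0])
        widths = [b.upper - b.lower]
        for _ in range(200):
            b = adapt_bounds(b, star)
            w = b.upper - b.lower
            assert np.all(w <= widths[-1] + 1e-12)
            assert np.all(b.lower < star) and np.all(star < b.upper)
            widths.append(w)

    def test_t2_intervals_stay_disjoint(self):
        b = default_bounds(3, 200.0)
        star = b.lower + 0.25 * (b.upper - b.lower)
        for _ in range(50):
            b = adapt_bounds(b, star)
        t2_lo, t2_hi = b.lower[1::2], b.upper[1::2]
        assert np.all(t2_hi[:-1] <= t2_lo[1:])


class TestInvert:
    def test_noiseless_mono_recovers_printed_phantom_values(self, te61):
        y = simulate_decay([(250.0, 80.0)], te61)
        fit = invert(DecayCurve(te61, y), e=1, config=OptimizerConfig(seed=0))
        a, t2 = fit.theta.components[0]
        assert a == pytest.approx(250.0, rel=1e-3)
        assert t2 == pytest.approx(80.0, rel=1e-3)

    def test_seeded_determinism(self, te61):
        y = simulate_decay([(100.0, 300.0)], te61)
        c = DecayCurve(te61, y)
        f1 = invert(c, e=1, config=OptimizerConfig(seed=42))
        f2 = invert(c, e=1, config=OptimizerConfig(seed=42))
        assert f1.theta.components == f2.theta.components
        assert f1.cls == f2.cls

    def test_matches_loglinear_oracle_on_random_curves(self, te61, rng):
        for i in range(10):
            a = rng.uniform(50, 500)
            t2 = rng.uniform(40, 1000)
            c = DecayCurve(te61, simulate_decay([(a, t2)], te61))
            swarm_fit = invert(c, e=1, config=OptimizerConfig(seed=i))
            oracle = loglinear_mono_fit(c)
            assert swarm_fit.theta.t2s[0] == pytest.approx(oracle.t2s[0], rel=1e-3)

    def test_gbest_monotone_nonincreasing(self, te61):
        y = simulate_decay([(100.0, 120.0), (50.0, 700.0)], te61)
        hist: list[float] = []
        invert(DecayCurve(te61, y), e=2, config=OptimizerConfig(seed=3, n_restarts=1),
               gbest_history=hist)
        assert len(hist) > 0
        assert np.all(np.diff(hist) <= 0)

    def test_result_within_bounds_and_sorted(self, te61):
        y = simulate_decay([(80.0, 90.0), (80.0, 500.0)], te61)
        b = default_bounds(2, float(y[0]))
        fit = invert(DecayCurve(te61, y), e=2, bounds=b, config=OptimizerConfig(seed=1))
        vec = fit.theta.as_vector()
        assert np.all(vec >= b.lower) and np.all(vec <= b.upper)
        assert np.all(np.diff(fit.theta.t2s) > 0)

    def test_mismatched_bounds_rejected(self, te61):
        y = simulate_decay([(10.0, 100.0)], te61)
        with pytest.raises(ValueError):
            invert(DecayCurve(te61, y), e=2, bounds=default_bounds(1, 10.0))

    def test_immune_engine_beats_plain_pso_on_tri_mixture(self, te61):
        # paired budget comparison: full engine vs bare swarm (no immune
        # operators, no receptor correction, no adaptation), median over seeds
        y = simulate_decay([(80.0, 80.0), (80.0, 200.0), (80.0, 600.0)], te61)
        c = DecayCurve(te61, y)
        full, plain = [], []
        for seed in range(5):
            f_full = invert(c, e=3, config=OptimizerConfig(seed=seed, n_restarts=1))
            plain_cfg = OptimizerConfig(
                seed=seed, n_restarts=1, clone_count=0, receptor_count=0,
                directional_count=0, covariance_count=0, projection_count=0,
                reseed_fraction=0.0, adapt_every=0,
            )
            f_plain = invert(c, e=3, config=plain_cfg)
            full.append(f_full.cls)
            plain.append(f_plain.cls)
        assert np.median(full) <= np.median(plain)


class TestFitnessVectorization:
    def test_batch_matches_objective(self, te61, rng):
        from mese_relaxo.relaxometry import ExpParams, objective_cls

        y = simulate_decay([(100.0, 150.0), (60.0, 500.0)], te61)
        curve = DecayCurve(te61, y, sigma=2.0)
        fn = _make_fitness(curve)
        X = rng.uniform([0, 10, 0, 10], [200, 800, 200, 800], size=(7, 4))
        batch = fn(X)
        for row, expected in zip(X, batch):
            theta = ExpParams.from_vector(row)
            assert objective_cls(theta, curve) == pytest.approx(expected, rel=1e-12)
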