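"""Chaotic immune particle-swarm inversion with adaptive component intervals.

Multi-exponential decay inversion is a small but nasty nonlinear
least-squares problem: the criterion surface has long curved valleys and,
for two or more components, local minima that trap derivative-based
solvers started from poor initial values. The engine here attacks it with
a global stochastic search built from four ingredients:

* **Particle swarm** (velocity/position updates toward each particle's own
  best and the global best),
* **chaotic coefficients**: the stochastic coefficients r1, r2 of the
  velocity update evolve by the logistic map r' = 4 r (1 - r) instead of
  fresh uniform draws, giving ergodic, non-repeating excitation,
* **immune operators**: the highest-affinity particles (affinity
  1/(1 + fitness)) are cloned; clones undergo chaotic mutation and
  arithmetic crossover and compete with their parents, with elitist
  selection so the global best never worsens,
* **adaptive component-interval bounds**: each parameter searches inside a
  physical interval (per-component amplitude and T2 ranges, the T2
  intervals non-overlapping and ascending); every K iterations the
  interval edges far from the incumbent best are pulled toward it by a
  logarithmic step, concentrating the swarm without ever excluding the
  incumbent.

The fitted components are returned sorted by ascending T2, which resolves
label switching between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .relaxometry import DecayCurve, ExpParams, FitResult, fit_metrics

__all__ = [
    "ComponentBounds",
    "OptimizerConfig",
    "SwarmState",
    "chaos_step",
    "pso_update",
    "immune_operators",
    "adapt_bounds",
    "invert",
    "default_bounds",
]

# Default non-overlapping T2 search intervals (ms) per component count,
# bracketing bound / semi-bound / free water pools of fruit tissue.
_DEFAULT_T2_INTERVALS = {
    1: ((1.0, 2000.0),),
    2: ((1.0, 200.0), (200.0, 2000.0)),
    3: ((1.0, 100.0), (100.0, 400.0), (400.0, 2000.0)),
    4: ((1.0, 60.0), (60.0, 200.0), (200.0, 600.0), (600.0, 2000.0)),
}

# Logistic-map fixed point; an absorbing state that must be reseeded.
_LOGISTIC_FIXED_POINT = 0.75


@dataclass(frozen=True)
class ComponentBounds:
    """Per-parameter search intervals plus interval-adaptation constants.

    ``lower``/``upper`` are flat vectors over [A1, T2_1, A2, T2_2, ...]
    with components in ascending T2 order; the T2 intervals must be
    pairwise non-overlapping. ``s`` is the threshold for interval updating
    and ``gamma`` the compression factor of the adaptive step.
    """

    lower: np.ndarray
    upper: np.ndarray
    s: float = 0.6
    gamma: float = 5.0

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size % 2 != 0 or lo.size == 0:
            raise ValueError("bounds must be flat even-length vectors of equal size")
        if np.any(lo >= hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if np.any(lo[0::2] < 0):
            raise ValueError("amplitude lower bounds must be nonnegative")
        if np.any(lo[1::2] <= 0):
            raise ValueError("T2 lower bounds must be positive")
        t2_lo, t2_hi = lo[1::2], hi[1::2]
        for k in range(t2_lo.size - 1):
            if t2_hi[k] > t2_lo[k + 1]:
                raise ValueError("T2 intervals must be non-overlapping and ascending")
        if not 0 < self.s < 1:
            raise ValueError("s must be in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def n_components(self) -> int:
        return self.lower.size // 2

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


def default_bounds(e: int, y0: float, s: float = 0.6, gamma: float = 5.0) -> ComponentBounds:
    """Default physical intervals for an e-component fit of a curve with
    first-echo signal y0: amplitudes in [0, 2 y0], T2 intervals bracketing
    the water-state ranges."""
    if e not in _DEFAULT_T2_INTERVALS:
        raise ValueError("e must be in 1..4")
    if y0 <= 0:
        raise ValueError("first-echo signal must be positive to scale bounds")
    lo = np.empty(2 * e)
    hi = np.empty(2 * e)
    for k, (t2_lo, t2_hi) in enumerate(_DEFAULT_T2_INTERVALS[e]):
        lo[2 * k], hi[2 * k] = 0.0, 2.0 * y0
        lo[2 * k + 1], hi[2 * k + 1] = t2_lo, t2_hi
    return ComponentBounds(lo, hi, s=s, gamma=gamma)


@dataclass
class OptimizerConfig:
    """Swarm hyperparameters. Defaults suit region-mean curves; voxel-wise
    maps use a lighter budget (see ``light()``)."""

    n_particles: int = 60
    max_iter: int = 500
    tol: float = 0.0                 # stop when gBest fitness <= tol
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    elite_fraction: float = 0.1
    clone_count: int = 3
    mutation_prob: float = 0.1
    crossover_prob: float = 0.5
    immune_every: int = 20           # clonal-selection cadence, iterations
    receptor_count: int = 5          # isotropic receptor probes of gBest per iteration
    projection_count: int = 10       # T2-jittered probes with closed-form amplitudes
    directional_count: int = 10      # valley-following probes along pBest differences
    covariance_count: int = 10       # probes shaped by the elite pBest covariance
    reseed_fraction: float = 0.1     # worst particles chaotically reinitialised per iteration
    adapt_every: int = 10            # bound-adaptation cadence, iterations
    n_restarts: int = 5              # independent swarm starts; best result kept
    restart_tol_rel: float = 1e-9    # early stop across restarts at this residual fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least two particles")
        for p in (self.mutation_prob, self.crossover_prob, self.elite_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.clone_count < 0:
            raise ValueError("clone_count must be nonnegative")

    @classmethod
    def light(cls, seed: int = 0) -> "OptimizerConfig":
        """Reduced budget for per-voxel mapping runs."""
        return cls(n_particles=25, max_iter=150, adapt_every=5, n_restarts=2, seed=seed)


@dataclass
class SwarmState:
    """Positions, velocities, personal/global bests and chaotic coefficients."""

    x: np.ndarray                    # (n, d) positions
    v: np.ndarray                    # (n, d) velocities
    fitness: np.ndarray              # (n,)
    pbest_x: np.ndarray
    pbest_f: np.ndarray
    gbest_x: np.ndarray
    gbest_f: float
    r1: float
    r2: float
    iteration: int = 0


def chaos_step(r: float, rng: np.random.Generator | None = None) -> float:
    """One logistic-map step r' = 4 r (1 - r).

    Inputs outside the open unit interval, and the absorbing fixed point
    0.75, are reseeded uniformly in (0, 1) away from the degenerate values
    {0, 0.25, 0.5, 0.75, 1}; this breaks the 0.5 -> 1 -> 0 trap one step
    after it closes.
    """
    if not 0.0 < r < 1.0 or r == _LOGISTIC_FIXED_POINT:
        rng = rng if rng is not None else np.random.default_rng()
        while True:
            r = float(rng.uniform(0.0, 1.0))
            if 0.0 < r < 1.0 and min(abs(r - d) for d in (0.25, 0.5, 0.75)) > 1e-9:
                break
    return 4.0 * r * (1.0 - r)


def _chaos_step_vec(r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Elementwise logistic step with reseeding of degenerate entries."""
    bad = ~((r > 0.0) & (r < 1.0)) | (r == _LOGISTIC_FIXED_POINT)
    if np.any(bad):
        r = r.copy()
        r[bad] = rng.uniform(0.01, 0.99, size=int(bad.sum()))
    return 4.0 * r * (1.0 - r)


def pso_update(
    x: np.ndarray,
    v: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    r1: float,
    r2: float,
    bounds: ComponentBounds,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity/position update with bound clipping.

    v' = w v + c1 r1 (pBest - x) + c2 r2 (gBest - x);  x' = clip(x + v').
    Dimensions that hit a bound have their velocity zeroed.
    Works on a single particle (d,) or a swarm (n, d).
    """
    v_new = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
    x_raw = x + v_new
    x_new = np.clip(x_raw, bounds.lower, bounds.upper)
    clipped = x_new != x_raw
    if np.any(clipped):
        v_new = np.where(clipped, 0.0, v_new)
    return x_new, v_new


def immune_operators(
    swarm: SwarmState,
    config: OptimizerConfig,
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    bounds: ComponentBounds,
    rng: np.random.Generator,
    chaos_pool: np.ndarray | None = None,
) -> SwarmState:
    """Clonal selection step: clone elites, mutate/cross clones, keep the best.

    The top ``elite_fraction`` of particles by affinity 1/(1 + fitness) are
    cloned ``clone_count`` times each. Clones undergo chaotic mutation
    (per-dimension replacement x_d <- lo_d + r (hi_d - lo_d), r from the
    logistic map, with probability ``mutation_prob``) and arithmetic
    crossover between random clone pairs with probability
    ``crossover_prob``. Parents and clones compete; the best n survive, so
    the population minimum fitness never increases.
    """
    n, d = swarm.x.shape
    n_elite = max(1, int(round(config.elite_fraction * n)))
    n_clones = n_elite * config.clone_count
    if n_clones == 0 and config.mutation_prob == 0 and config.crossover_prob == 0:
        return swarm
    if n_clones == 0:
        return swarm

    affinity = 1.0 / (1.0 + swarm.fitness)
    elite_idx = np.argsort(affinity)[::-1][:n_elite]
    parents = np.repeat(elite_idx, config.clone_count)
    clones = swarm.x[parents].copy()

    # Chaotic mutation: replacement inside the current intervals.
    if chaos_pool is None:
        chaos_pool = rng.uniform(0.01, 0.99, size=clones.shape)
    chaos_pool = _chaos_step_vec(chaos_pool, rng)
    mut_mask = rng.random(clones.shape) < config.mutation_prob
    span = bounds.upper - bounds.lower
    mutated = bounds.lower + chaos_pool * span
    clones = np.where(mut_mask, mutated, clones)

    # Arithmetic crossover between random clone pairs.
    if n_clones >= 2 and config.crossover_prob > 0:
        pairs = rng.permutation(n_clones)
        for a, b in zip(pairs[0::2], pairs[1::2]):
            if rng.random() < config.crossover_prob:
                lam = rng.random()
                xa, xb = clones[a].copy(), clones[b].copy()
                clones[a] = lam * xa + (1.0 - lam) * xb
                clones[b] = lam * xb + (1.0 - lam) * xa

    clone_fit = fitness_fn(clones)

    # Elitist selection among parents + clones.
    all_x = np.vstack([swarm.x, clones])
    all_v = np.vstack([swarm.v, swarm.v[parents]])
    all_f = np.concatenate([swarm.fitness, clone_fit])
    all_pbx = np.vstack([swarm.pbest_x, swarm.pbest_x[parents]])
    all_pbf = np.concatenate([swarm.pbest_f, swarm.pbest_f[parents]])
    keep = np.argsort(all_f, kind="stable")[:n]

    x, v, f = all_x[keep], all_v[keep], all_f[keep]
    pbx, pbf = all_pbx[keep], all_pbf[keep]
    better = f < pbf
    pbx[better] = x[better]
    pbf[better] = f[better]

    gbest_x, gbest_f = swarm.gbest_x, swarm.gbest_f
    k = int(np.argmin(pbf))
    if pbf[k] < gbest_f:
        gbest_f = float(pbf[k])
        gbest_x = pbx[k].copy()

    return replace(
        swarm, x=x, v=v, fitness=f, pbest_x=pbx, pbest_f=pbf, gbest_x=gbest_x, gbest_f=gbest_f
    )


def adapt_bounds(
    bounds: ComponentBounds,
    gbest: np.ndarray,
    s: float | None = None,
    gamma: float | None = None,
) -> ComponentBounds:
    """Peak-correction interval update around the incumbent best.

    Per dimension, with interval width W = hi - lo and normalised margins
    m1 = (hi - x*)/W, m2 = (x* - lo)/W: when s < m1 < 1 the upper bound is
    pulled toward x* by |ln m1| / gamma of the current width, and likewise
    the lower bound when s < m2 < 1. Dimensions where the incumbent sits on
    or outside a bound are left unchanged; the incumbent always remains
    strictly inside the updated interval, and T2 intervals can only shrink
    so they stay non-overlapping.
    """
    s = bounds.s if s is None else s
    gamma = bounds.gamma if gamma is None else gamma
    lo = bounds.lower.copy()
    hi = bounds.upper.copy()
    gbest = np.asarray(gbest, dtype=float)
    if gbest.shape != lo.shape:
        raise ValueError("gbest must match the bounds dimensionality")
    width = hi - lo
    inside = (gbest > lo) & (gbest < hi)
    m1 = np.where(inside, (hi - gbest) / width, 0.0)
    m2 = np.where(inside, (gbest - lo) / width, 0.0)

    move_hi = inside & (m1 > s) & (m1 < 1.0)
    move_lo = inside & (m2 > s) & (m2 < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        step_hi = np.where(move_hi, np.abs(np.log(np.where(move_hi, m1, 1.0))) / gamma * width, 0.0)
        step_lo = np.where(move_lo, np.abs(np.log(np.where(move_lo, m2, 1.0))) / gamma * width, 0.0)
    hi_new = hi - step_hi
    lo_new = lo + step_lo
    # Never exclude the incumbent: keep a sliver of room on each side.
    margin = 1e-12 * np.maximum(width, 1.0)
    hi_new = np.where(move_hi, np.maximum(hi_new, gbest + margin), hi)
    lo_new = np.where(move_lo, np.minimum(lo_new, gbest - margin), lo)
    return ComponentBounds(lo_new, hi_new, s=bounds.s, gamma=bounds.gamma)


# ---------------------------------------------------------------------------
# Full inversion


def _make_fitness(curve: DecayCurve) -> Callable[[np.ndarray], np.ndarray]:
    te = curve.te
    y = curve.y
    inv_two_sigma2 = 1.0 / (2.0 * curve.sigma**2)

    def fitness(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        amps = x[:, 0::2]                       # (n, e)
        t2s = x[:, 1::2]
        decay = np.exp(-te[None, :, None] / t2s[:, None, :])   # (n, T, e)
        model = np.einsum("nte,ne->nt", decay, amps)
        resid = model - y[None, :]
        return np.einsum("nt,nt->n", resid, resid) * inv_two_sigma2

    return fitness


def _project_amplitudes(
    t2s: np.ndarray, curve: DecayCurve, bounds: ComponentBounds
) -> np.ndarray:
    """Best amplitudes for fixed T2s: the criterion is linear in A, so the
    subproblem has a closed-form least-squares solution (clipped into the
    amplitude intervals)."""
    design = np.exp(-curve.te[:, None] / t2s[None, :])
    amps, *_ = np.linalg.lstsq(design, curve.y, rcond=None)
    return np.clip(amps, bounds.lower[0::2], bounds.upper[0::2])


def _run_swarm(
    curve: DecayCurve,
    e: int,
    bounds: ComponentBounds,
    config: OptimizerConfig,
    seed,
    gbest_history: list[float] | None = None,
) -> tuple[np.ndarray, float, int]:
    """One seeded swarm run; returns (gbest position, gbest fitness, iterations)."""
    rng = np.random.default_rng(seed)
    d = 2 * e
    fitness_fn = _make_fitness(curve)

    x = rng.uniform(bounds.lower, bounds.upper, size=(config.n_particles, d))
    v = np.zeros_like(x)
    f = fitness_fn(x)
    k = int(np.argmin(f))
    swarm = SwarmState(
        x=x, v=v, fitness=f, pbest_x=x.copy(), pbest_f=f.copy(),
        gbest_x=x[k].copy(), gbest_f=float(f[k]),
        r1=chaos_step(rng.uniform(0.01, 0.99), rng),
        r2=chaos_step(rng.uniform(0.01, 0.99), rng),
    )
    n_elite = max(1, int(round(config.elite_fraction * config.n_particles)))
    chaos_pool = rng.uniform(0.01, 0.99, size=(n_elite * max(config.clone_count, 1), d))
    n_reseed = int(round(config.reseed_fraction * config.n_particles))
    gf_at_last_adapt = swarm.gbest_f

    def offer(probes: np.ndarray) -> None:
        # Accept a probe batch into gBest if it improves it.
        probes = np.clip(probes, bounds.lower, bounds.upper)
        pf = fitness_fn(probes)
        j = int(np.argmin(pf))
        if pf[j] < swarm.gbest_f:
            swarm.gbest_f = float(pf[j])
            swarm.gbest_x = probes[j].copy()

    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        frac = it / config.max_iter
        w = config.w_start + (config.w_end - config.w_start) * frac

        x, v = pso_update(
            swarm.x, swarm.v, swarm.pbest_x, swarm.gbest_x,
            w, config.c1, config.c2, swarm.r1, swarm.r2, bounds,
        )
        if n_reseed > 0:
            # Chaotic regeneration of the worst particles keeps the swarm
            # spread out (new particles from the chaos operator).
            worst = np.argsort(swarm.fitness)[-n_reseed:]
            span = bounds.upper - bounds.lower
            x[worst] = bounds.lower + rng.random((n_reseed, x.shape[1])) * span
            v[worst] = 0.0
        f = fitness_fn(x)
        better = f < swarm.pbest_f
        swarm.pbest_x[better] = x[better]
        swarm.pbest_f[better] = f[better]
        swarm.x, swarm.v, swarm.fitness = x, v, f
        k = int(np.argmin(swarm.pbest_f))
        if swarm.pbest_f[k] < swarm.gbest_f:
            swarm.gbest_f = float(swarm.pbest_f[k])
            swarm.gbest_x = swarm.pbest_x[k].copy()

        if config.clone_count > 0 and config.immune_every > 0 and it % config.immune_every == 0:
            # Clonal selection runs on a cadence: applied every iteration its
            # elitist survivor step collapses swarm diversity faster than the
            # chaotic reseeding can restore it.
            chaos_pool = _chaos_step_vec(chaos_pool, rng)
            swarm = immune_operators(
                swarm, config, fitness_fn, bounds, rng, chaos_pool=chaos_pool
            )

        # Receptor correction of the incumbent best: three probe families
        # refine gBest without ever worsening it.
        d_ = x.shape[1]
        if config.directional_count > 0:
            # Valley-following steps along differences of personal bests.
            a = rng.integers(0, config.n_particles, config.directional_count)
            b = rng.integers(0, config.n_particles, config.directional_count)
            steps = rng.uniform(-1.0, 1.0, (config.directional_count, 1))
            offer(swarm.gbest_x[None, :] + steps * (swarm.pbest_x[a] - swarm.pbest_x[b]))
        if config.covariance_count > 0 and config.n_particles >= 4:
            # Probes shaped like the elite cloud, capturing the local
            # curvature anisotropy of the criterion surface.
            top = np.argsort(swarm.pbest_f)[: max(4, n_elite * 2)]
            cov = np.cov(swarm.pbest_x[top].T)
            cov += 1e-12 * np.eye(d_) * float(np.mean((bounds.upper - bounds.lower) ** 2))
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol = None
            if chol is not None:
                z = rng.standard_normal((config.covariance_count, d_))
                offer(swarm.gbest_x[None, :] + z @ chol.T)
        if config.receptor_count > 0:
            # Isotropic probes with radius decaying from the interval width
            # to a fine scale over the run.
            width = bounds.upper - bounds.lower
            scale = width * 10.0 ** (-4.0 * frac)
            z = rng.standard_normal((config.receptor_count, d_))
            offer(swarm.gbest_x[None, :] + scale[None, :] * z)
        if config.projection_count > 0:
            # Variable-projection probes: jitter the incumbent T2s in log
            # space (radius decaying over the run) and set each probe's
            # amplitudes to their closed-form optimum — the criterion is
            # linear in the amplitudes, so this searches only T2 space.
            t2_lo, t2_hi = bounds.lower[1::2], bounds.upper[1::2]
            t2_g = swarm.gbest_x[1::2]
            jitter = 0.3 * 10.0 ** (-3.0 * frac)
            probes = np.empty((config.projection_count, d_))
            for row in range(config.projection_count):
                t2p = np.clip(
                    t2_g * np.exp(jitter * rng.standard_normal(t2_g.size)), t2_lo, t2_hi
                )
                probes[row, 0::2] = _project_amplitudes(t2p, curve, bounds)
                probes[row, 1::2] = t2p
            offer(probes)

        swarm.r1 = chaos_step(swarm.r1, rng)
        swarm.r2 = chaos_step(swarm.r2, rng)
        swarm.iteration = it

        if config.adapt_every > 0 and it % config.adapt_every == 0:
            # Compress intervals only once the incumbent has stalled, so the
            # adaptation zooms in on a settled optimum instead of locking in
            # an early transient.
            if gf_at_last_adapt - swarm.gbest_f < 1e-3 * max(swarm.gbest_f, 1e-300):
                bounds = adapt_bounds(bounds, swarm.gbest_x)
                swarm.x = np.clip(swarm.x, bounds.lower, bounds.upper)
                clipped_pb = np.clip(swarm.pbest_x, bounds.lower, bounds.upper)
                moved = np.any(clipped_pb != swarm.pbest_x, axis=1)
                if np.any(moved):
                    swarm.pbest_x = clipped_pb
                    swarm.pbest_f[moved] = fitness_fn(clipped_pb[moved])
            gf_at_last_adapt = swarm.gbest_f

        if gbest_history is not None:
            gbest_history.append(swarm.gbest_f)
        if swarm.gbest_f <= config.tol:
            break

    return swarm.gbest_x, swarm.gbest_f, n_iter


def invert(
    curve: DecayCurve,
    e: int = 1,
    bounds: ComponentBounds | None = None,
    config: OptimizerConfig | None = None,
    gbest_history: list[float] | None = None,
) -> FitResult:
    """Fit an e-component decay model to a curve with the full engine.

    Runs up to ``n_restarts`` independently seeded swarms, each iterating
    {evaluate criterion -> swarm update -> immune operators -> receptor
    correction -> logistic step on r1, r2 -> interval adaptation every K
    iterations} until ``max_iter`` or the fitness tolerance; restarts stop
    early once the residual falls below ``restart_tol_rel`` of the signal
    energy. Returns a :class:`~mese_relaxo.relaxometry.FitResult` with
    components sorted by ascending T2 and goodness-of-fit metrics on the
    fitted curve; identical inputs and seed give identical output.
    """
    config = config if config is not None else OptimizerConfig()
    if bounds is None:
        bounds = default_bounds(e, float(curve.y[0]))
    if bounds.n_components != e:
        raise ValueError("bounds dimensionality does not match e")
    if curve.n_echo < 2 * e:
        raise ValueError("curve has too few echoes to identify the model")

    # A residual below this fraction of the (noise-scaled) signal energy
    # marks a solved curve; further restarts cannot meaningfully improve it.
    energy = float(np.sum((curve.y / curve.sigma) ** 2)) / 2.0
    good_enough = config.restart_tol_rel * energy

    seeds = np.random.SeedSequence(config.seed).spawn(max(1, config.n_restarts))
    best_x: np.ndarray | None = None
    best_f = np.inf
    total_iter = 0
    for seq in seeds:
        gx, gf, n_it = _run_swarm(curve, e, bounds, config, seq, gbest_history)
        total_iter += n_it
        if gf < best_f:
            best_f = gf
            best_x = gx
        if best_f <= max(config.tol, good_enough):
            break

    theta = ExpParams.from_vector(best_x).sorted_by_t2()
    r2, rmse = fit_metrics(curve, theta)
    return FitResult(
        theta=theta,
        cls=float(best_f),
        r2=r2,
        rmse=rmse,
        n_iter=total_iter,
        converged=best_f <= max(config.tol, good_enough) or config.tol == 0.0,
    )
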