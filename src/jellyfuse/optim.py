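"""Box-constrained metaheuristic optimizers.

Implements the artificial jellyfish search (AJS) swarm optimizer together
with real-coded genetic-algorithm (GA) and particle-swarm (PSO) baselines.
All three minimize a real-valued objective over a rectangular search space
and return the best-so-far trajectory.

AJS alternates two movement regimes, switched by a decaying stochastic
time-control function ``fTC``:

* **ocean-current drift** — the swarm drifts along the vector from the
  population mean toward the incumbent best position;
* **swarm motion** — each jellyfish either takes a small *passive* step
  around its own location or an *active* step toward a randomly chosen,
  better-performing partner.

Positions leaving the box re-enter from the opposite bound (toroidal
wrapping), so feasibility is maintained without clipping bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "AJSConfig",
    "GAConfig",
    "PSOConfig",
    "JellyfishPopulation",
    "OptimizationResult",
    "OptimizationError",
    "ocean_current",
    "drift_step",
    "passive_step",
    "active_step",
    "time_control",
    "wrap_bounds",
    "ajs_optimize",
    "ga_optimize",
    "pso_optimize",
    "OPTIMIZERS",
]


class OptimizationError(RuntimeError):
    """Raised when an optimizer cannot proceed (e.g. non-finite cost)."""


@dataclass(frozen=True)
class SearchSpace:
    """A rectangular (box) search domain.

    Parameters
    ----------
    dim : int
        Number of decision variables.
    lower, upper : array-like of shape (dim,)
        Per-dimension bounds; ``lower[d] < upper[d]`` for every ``d``.
    """

    dim: int
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if self.dim <= 0:
            raise ValueError("dim must be a positive integer")
        if lower.shape != (self.dim,) or upper.shape != (self.dim,):
            raise ValueError("bound vectors must have length dim")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        """The unit hypercube [0, 1]^dim (the weight-vector domain)."""
        return cls(dim, np.zeros(dim), np.ones(dim))

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchSpace":
        return cls(dim, np.full(dim, float(lo)), np.full(dim, float(hi)))

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class AJSConfig:
    """Jellyfish-search settings.

    ``phi`` is the distribution coefficient of the ocean-current drift and
    ``omega`` the motion coefficient scaling passive steps; neither has a
    published value for this application so the defaults follow the original
    optimizer (3 and 0.1).  ``c0`` is the constant against which the
    time-control function is compared.
    """

    pop_size: int = 10
    max_iter: int = 50
    phi: float = 3.0
    omega: float = 0.1
    c0: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.phi <= 0 or self.omega <= 0:
            raise ValueError("phi and omega must be positive")
        if not 0.0 < self.c0 < 1.0:
            raise ValueError("c0 must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA with roulette-wheel selection.

    Crossover is uniform-arithmetic (per-gene convex blend), mutation adds
    Gaussian noise with standard deviation ``mutation_sigma_frac`` of the
    box span, and one elite survives each generation unchanged.
    """

    pop_size: int = 10
    max_iter: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_sigma_frac: float = 0.1
    n_elite: int = 1
    seed: int = 0


@dataclass(frozen=True)
class PSOConfig:
    """PSO with damped inertia (w *= damping per iteration) and velocity
    clamped to the box span."""

    pop_size: int = 10
    max_iter: int = 50
    inertia: float = 1.0
    damping: float = 0.99
    c1: float = 1.5
    c2: float = 2.0
    seed: int = 0


@dataclass
class JellyfishPopulation:
    """Mutable swarm state: candidate positions, their costs and the
    incumbent best."""

    positions: np.ndarray
    costs: np.ndarray
    best_position: np.ndarray
    best_cost: float
    t: int = 0

    @property
    def pop_size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass
class OptimizationResult:
    """Outcome of a single optimizer run.

    ``trace`` holds the best-so-far cost after initialization and after each
    iteration, so it is monotonically non-increasing and its last entry
    equals ``best_cost``.
    """

    best_position: np.ndarray
    best_cost: float
    trace: np.ndarray
    n_evals: int

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(len(self.trace)), "best_cost": self.trace}
        )


def _check_finite_cost(c: float, x: np.ndarray) -> float:
    c = float(c)
    if not math.isfinite(c):
        raise OptimizationError(
            f"objective returned non-finite cost {c!r} at position {x!r}"
        )
    return c


# ---------------------------------------------------------------------------
# AJS movement operators
# ---------------------------------------------------------------------------

def ocean_current(population: JellyfishPopulation, phi: float, rng) -> np.ndarray:
    """Drift direction toward the incumbent best.

    Returns ``best − phi · u · mean(positions)`` with a single scalar
    ``u ~ U(0, 1)`` shared across dimensions.
    """
    if population.positions.size == 0:
        raise OptimizationError("ocean_current requires a non-empty population")
    if phi <= 0:
        raise ValueError("phi must be positive")
    u = float(rng.uniform())
    mean_loc = population.positions.mean(axis=0)
    return population.best_position - phi * u * mean_loc


def drift_step(position: np.ndarray, current: np.ndarray, rng) -> np.ndarray:
    """Move along the ocean current by a random fraction ``u ~ U(0, 1)``."""
    position = np.asarray(position, dtype=float)
    current = np.asarray(current, dtype=float)
    if position.shape != current.shape:
        raise ValueError("position and current must have the same length")
    return position + float(rng.uniform()) * current


def passive_step(position: np.ndarray, space: SearchSpace, omega: float, rng) -> np.ndarray:
    """Small local exploration step of size ``omega`` relative to the box
    span, with an independent uniform draw per dimension."""
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dim,):
        raise ValueError("position length must equal space.dim")
    u = rng.uniform(size=space.dim)
    return position + omega * u * space.span


def active_step(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    cost_i: float,
    cost_j: float,
    rng,
) -> np.ndarray:
    """Move jellyfish *i* toward partner *j* when *j* is at least as good
    (minimization: ``cost_i >= cost_j``), away from it otherwise."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    if pos_i.shape != pos_j.shape:
        raise ValueError("positions must have the same length")
    if cost_i >= cost_j:
        direction = pos_j - pos_i
    else:
        direction = pos_i - pos_j
    return pos_i + float(rng.uniform()) * direction


def time_control(t: int, max_iter: int, rng) -> float:
    """Decaying stochastic switch ``|(1 − t/max_iter) · (2u − 1)|`` in [0, 1).

    The absolute value keeps the switch inside its stated (0, 1) range so the
    drift branch (``fTC >= c``) is reachable; it is exactly 0 at the final
    iteration.
    """
    if not 1 <= t <= max_iter:
        raise ValueError(f"iteration index t={t} outside [1, {max_iter}]")
    u = float(rng.uniform())
    return abs((1.0 - t / max_iter) * (2.0 * u - 1.0))


def wrap_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Re-enter the box from the opposite bound (toroidal wrapping).

    A coordinate above the upper bound re-enters at the lower bound offset
    by its excess, and symmetrically below; applied repeatedly until the
    coordinate is in range.  In-range coordinates are returned unchanged.
    """
    x = np.asarray(position, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise OptimizationError(f"cannot wrap non-finite position {position!r}")
    span = space.span
    # closed-form modular wrap (equivalent to repeated single-bound shifts)
    out = (x < space.lower) | (x > space.upper)
    x[out] = space.lower[out] + np.mod(x[out] - space.lower[out], span[out])
    return x


# ---------------------------------------------------------------------------
# Full optimizers
# ---------------------------------------------------------------------------

def _init_population(objective, space: SearchSpace, pop_size: int, rng):
    positions = rng.uniform(space.lower, space.upper, size=(pop_size, space.dim))
    costs = np.array([_check_finite_cost(objective(p), p) for p in positions])
    best = int(np.argmin(costs))
    return positions, costs, best


def ajs_optimize(objective, space: SearchSpace, config: AJSConfig | None = None) -> OptimizationResult:
    """Run the jellyfish-search loop and return the best solution found.

    Per jellyfish per iteration: draw the time-control value; if it reaches
    ``c0`` take an ocean-current drift step, otherwise take a passive step
    with probability equal to the time-control value and an active step
    toward a random partner otherwise.  Positions are wrapped back into the
    box after every move; a move is accepted only if it improves that
    jellyfish's cost (greedy acceptance, as in the original swarm), and the
    incumbent best is tracked across all evaluations.
    """
    config = config or AJSConfig()
    rng = np.random.default_rng(config.seed)
    positions, costs, best = _init_population(objective, space, config.pop_size, rng)
    pop = JellyfishPopulation(
        positions=positions,
        costs=costs,
        best_position=positions[best].copy(),
        best_cost=float(costs[best]),
    )
    n_evals = config.pop_size
    trace = [pop.best_cost]

    for t in range(1, config.max_iter + 1):
        pop.t = t
        for i in range(config.pop_size):
            ftc = time_control(t, config.max_iter, rng)
            if ftc >= config.c0:
                current = ocean_current(pop, config.phi, rng)
                new_pos = drift_step(pop.positions[i], current, rng)
            elif float(rng.uniform()) > (1.0 - ftc):
                new_pos = passive_step(pop.positions[i], space, config.omega, rng)
            else:
                j = int(rng.integers(config.pop_size - 1))
                if j >= i:
                    j += 1
                new_pos = active_step(
                    pop.positions[i], pop.positions[j], pop.costs[i], pop.costs[j], rng
                )
            new_pos = wrap_bounds(new_pos, space)
            cost = _check_finite_cost(objective(new_pos), new_pos)
            n_evals += 1
            if cost < pop.costs[i]:
                pop.positions[i] = new_pos
                pop.costs[i] = cost
                if cost < pop.best_cost:
                    pop.best_cost = cost
                    pop.best_position = new_pos.copy()
        trace.append(pop.best_cost)

    return OptimizationResult(
        best_position=pop.best_position,
        best_cost=pop.best_cost,
        trace=np.asarray(trace),
        n_evals=n_evals,
    )


def _roulette_probabilities(costs: np.ndarray) -> np.ndarray:
    # minimization: fitness is the gap to the worst cost, with a floor so
    # an all-equal population degrades to uniform selection
    fitness = (costs.max() - costs) + 1e-12
    return fitness / fitness.sum()


def ga_optimize(objective, space: SearchSpace, config: GAConfig | None = None) -> OptimizationResult:
    """Real-coded genetic algorithm with roulette-wheel selection."""
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    positions, costs, best = _init_population(objective, space, config.pop_size, rng)
    best_position = positions[best].copy()
    best_cost = float(costs[best])
    n_evals = config.pop_size
    trace = [best_cost]
    sigma = config.mutation_sigma_frac * space.span

    for _ in range(config.max_iter):
        probs = _roulette_probabilities(costs)
        elite_order = np.argsort(costs)[: config.n_elite]
        children = [positions[k].copy() for k in elite_order]
        while len(children) < config.pop_size:
            pa, pb = rng.choice(config.pop_size, size=2, p=probs)
            child = positions[pa].copy()
            if rng.uniform() < config.crossover_prob:
                alpha = rng.uniform(size=space.dim)
                child = alpha * positions[pa] + (1.0 - alpha) * positions[pb]
            mutate = rng.uniform(size=space.dim) < config.mutation_prob
            child = child + mutate * rng.normal(0.0, 1.0, size=space.dim) * sigma
            children.append(np.clip(child, space.lower, space.upper))
        positions = np.vstack(children)
        costs = np.array([_check_finite_cost(objective(p), p) for p in positions])
        n_evals += config.pop_size
        k = int(np.argmin(costs))
        if costs[k] < best_cost:
            best_cost = float(costs[k])
            best_position = positions[k].copy()
        trace.append(best_cost)

    return OptimizationResult(best_position, best_cost, np.asarray(trace), n_evals)


def pso_optimize(objective, space: SearchSpace, config: PSOConfig | None = None) -> OptimizationResult:
    """Particle swarm with damped inertia and span-clamped velocities."""
    config = config or PSOConfig()
    rng = np.random.default_rng(config.seed)
    positions, costs, best = _init_population(objective, space, config.pop_size, rng)
    velocities = np.zeros_like(positions)
    pbest_pos = positions.copy()
    pbest_cost = costs.copy()
    gbest_pos = positions[best].copy()
    gbest_cost = float(costs[best])
    n_evals = config.pop_size
    trace = [gbest_cost]
    w = config.inertia
    vmax = space.span  # velocity clamp: one full box span per step

    for _ in range(config.max_iter):
        r1 = rng.uniform(size=positions.shape)
        r2 = rng.uniform(size=positions.shape)
        velocities = (
            w * velocities
            + config.c1 * r1 * (pbest_pos - positions)
            + config.c2 * r2 * (gbest_pos - positions)
        )
        velocities = np.clip(velocities, -vmax, vmax)
        positions = np.clip(positions + velocities, space.lower, space.upper)
        costs = np.array([_check_finite_cost(objective(p), p) for p in positions])
        n_evals += config.pop_size
        improved = costs < pbest_cost
        pbest_pos[improved] = positions[improved]
        pbest_cost[improved] = costs[improved]
        k = int(np.argmin(pbest_cost))
        if pbest_cost[k] < gbest_cost:
            gbest_cost = float(pbest_cost[k])
            gbest_pos = pbest_pos[k].copy()
        trace.append(gbest_cost)
        w *= config.damping

    return OptimizationResult(gbest_pos, gbest_cost, np.asarray(trace), n_evals)


OPTIMIZERS = {"ajs": ajs_optimize, "ga": ga_optimize, "pso": pso_optimize}
OPTIMIZER_CONFIGS = {"ajs": AJSConfig, "ga": GAConfig, "pso": PSOConfig}


def make_optimizer_config(optimizer: str, **kwargs):
    """Build the config dataclass for a named optimizer, ignoring keys the
    optimizer does not recognize (so one run document can serve all three)."""
    cls = OPTIMIZER_CONFIGS[optimizer]
    valid = {f for f in cls.__dataclass_fields__}
    return cls(**{k: v for k, v in kwargs.items() if k in valid})
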