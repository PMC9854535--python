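"""Artificial hummingbird algorithm (AHA) for bounded continuous minimization.

The algorithm maintains a population of *food sources* (candidate solutions)
and a *visit table* recording, for every (bird, source) pair, how many
iterations have elapsed since that bird last visited that source.  Each
iteration every bird either performs **guided foraging** (a move toward the
remembered source with the highest visit level, i.e. the longest-neglected
one, ties broken by better fitness) or **territorial foraging** (a local
perturbation around its own source), each with probability 1/2.  Every
``migration_period`` iterations the worst source is abandoned and replaced by
a fresh uniform-random position (**migration foraging**).

Moves are masked by a random *flight* pattern: axial (one coordinate),
diagonal (a random subset of 2..ceil(r1*(d-2))+1 coordinates) or
omnidirectional (all coordinates).  Candidates falling outside the box bounds
are clamped coordinate-wise.  Lower objective = better ("more nectar").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("mitoboost")

AXIAL = "axial"
DIAGONAL = "diagonal"
OMNIDIRECTIONAL = "omnidirectional"
FLIGHT_KINDS = (AXIAL, DIAGONAL, OMNIDIRECTIONAL)


class InvalidConfigError(ValueError):
    """Raised for structurally invalid optimizer configuration."""


class InvalidSpaceError(ValueError):
    """Raised when a search space has crossed or malformed bounds."""


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box in R^d: low[i] <= x[i] <= up[i]."""

    low: np.ndarray
    up: np.ndarray

    def __post_init__(self) -> None:
        low = np.atleast_1d(np.asarray(self.low, dtype=float))
        up = np.atleast_1d(np.asarray(self.up, dtype=float))
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "up", up)
        if low.shape != up.shape or low.ndim != 1:
            raise InvalidSpaceError("bound vectors must be 1-D and equal length")
        if np.any(low > up):
            raise InvalidSpaceError("lower bound exceeds upper bound")

    @property
    def d(self) -> int:
        return self.low.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        clipped = np.clip(x, self.low, self.up)
        if np.any(clipped != x):
            logger.debug("candidate clamped to bounds")
        return clipped

    def uniform(self, rng: np.random.Generator) -> np.ndarray:
        r = rng.uniform(size=self.d)
        return self.low + r * (self.up - self.low)


@dataclass
class Population:
    """Food-source positions (n x d) and their objective values (n,)."""

    positions: np.ndarray
    fitness: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))


@dataclass(frozen=True)
class AHBAConfig:
    n: int = 20
    max_iters: int = 200
    migration_period: int | None = None  # default 2n, set in optimize()
    flight_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    guided_prob: float = 0.5  # per-bird probability of guided vs territorial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidConfigError("population size must be at least 2")
        if self.max_iters < 1:
            raise InvalidConfigError("iteration budget must be positive")
        if self.migration_period is not None and self.migration_period < 1:
            raise InvalidConfigError("migration_period must be >= 1")
        if not math.isclose(sum(self.flight_probs), 1.0, abs_tol=1e-9):
            raise InvalidConfigError("flight_probs must sum to 1")


def _check_fitness(value: float, x: np.ndarray) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"objective returned non-finite value {value!r} at position {x.tolist()}")
    return value


def initialize_population(
    space: SearchSpace, n: int, objective, rng: np.random.Generator
) -> Population:
    """Draw n food sources uniformly in the box and evaluate them.

    Each coordinate is low + r*(up-low) with an independent uniform r.
    """
    if n < 2:
        raise InvalidConfigError("population size must be at least 2")
    positions = np.stack([space.uniform(rng) for _ in range(n)])
    fitness = np.array([_check_fitness(objective(x), x) for x in positions])
    return Population(positions=positions, fitness=fitness)


def init_visit_table(n: int) -> np.ndarray:
    """n x n visit-level table: 0 off the diagonal, NaN (null) on it."""
    if n < 2:
        raise InvalidConfigError("visit table needs at least 2 birds")
    vt = np.zeros((n, n))
    np.fill_diagonal(vt, np.nan)
    return vt


def sample_flight_direction(
    kind: str, d: int, rng: np.random.Generator, r1: float | None = None
) -> np.ndarray:
    """Binary mask of the coordinates touched by one flight.

    axial: exactly one active coordinate; omnidirectional: all d; diagonal:
    k = max(2, ceil(r1*(d-2))+1) distinct random coordinates (requires d >= 3,
    otherwise falls back to axial).
    """
    if d < 1:
        raise InvalidConfigError("dimension must be positive")
    D = np.zeros(d)
    if kind == OMNIDIRECTIONAL:
        D[:] = 1.0
    elif kind == AXIAL:
        D[rng.integers(d)] = 1.0
    elif kind == DIAGONAL:
        if d < 3:
            logger.debug("diagonal flight requested with d=%d < 3; using axial", d)
            return sample_flight_direction(AXIAL, d, rng)
        if r1 is None:
            r1 = float(rng.uniform())
        k = max(2, math.ceil(r1 * (d - 2)) + 1)
        active = rng.choice(d, size=k, replace=False)
        D[active] = 1.0
    else:
        raise InvalidConfigError(f"unknown flight kind {kind!r}")
    return D


def _sample_flight(d: int, flight_probs, rng: np.random.Generator) -> np.ndarray:
    kind = FLIGHT_KINDS[rng.choice(3, p=np.asarray(flight_probs))]
    return sample_flight_direction(kind, d, rng)


def update_visit_table(
    vt: np.ndarray,
    i: int,
    j_visited: int | None,
    replaced_source: int | None = None,
) -> np.ndarray:
    """Canonical visit bookkeeping after bird i acts (in place).

    Bird i's visit levels toward every other source grow by one iteration;
    the source it just visited resets to 0.  If a source's position was
    replaced (bird ``replaced_source`` moved, or migration), every other bird
    has never seen the new source, so its visit level toward it is set above
    that bird's current row maximum.
    """
    n = vt.shape[0]
    if j_visited is not None and i == j_visited:
        raise ValueError("a bird cannot visit its own source (diagonal is null)")
    row = vt[i]
    mask = ~np.isnan(row)
    row[mask] += 1
    if j_visited is not None:
        row[j_visited] = 0.0
    if replaced_source is not None:
        for b in range(n):
            if b == replaced_source:
                continue
            vt[b, replaced_source] = np.nanmax(vt[b]) + 1
    return vt


def _select_target(vt: np.ndarray, pop: Population, i: int) -> int:
    """Source with the highest visit level for bird i; ties -> best fitness."""
    row = vt[i]
    level = np.where(np.isnan(row), -np.inf, row)
    top = np.flatnonzero(level == level.max())
    return int(top[np.argmin(pop.fitness[top])])


def guided_foraging_step(
    pop: Population,
    vt: np.ndarray,
    i: int,
    objective,
    space: SearchSpace,
    rng: np.random.Generator,
    flight_probs=(1 / 3, 1 / 3, 1 / 3),
    a: float | None = None,
    D: np.ndarray | None = None,
) -> None:
    """Move bird i toward its remembered target source (in place).

    Candidate v = x_target + a * D o (x_i - x_target), a ~ N(0,1); accepted
    only on strict fitness improvement.  ``a`` and ``D`` may be pinned for
    testing.
    """
    j = _select_target(vt, pop, i)
    if a is None:
        a = float(rng.standard_normal())
    if D is None:
        D = _sample_flight(space.d, flight_probs, rng)
    x_i = pop.positions[i]
    x_t = pop.positions[j]
    v = space.clamp(x_t + a * D * (x_i - x_t))
    fv = _check_fitness(objective(v), v)
    if fv < pop.fitness[i]:
        pop.positions[i] = v
        pop.fitness[i] = fv
        update_visit_table(vt, i, j, replaced_source=i)
    else:
        update_visit_table(vt, i, j)


def territorial_foraging_step(
    pop: Population,
    vt: np.ndarray,
    i: int,
    objective,
    space: SearchSpace,
    rng: np.random.Generator,
    flight_probs=(1 / 3, 1 / 3, 1 / 3),
    b: float | None = None,
    D: np.ndarray | None = None,
) -> None:
    """Perturb bird i within its own territory: v = x_i + b * D o x_i."""
    if b is None:
        b = float(rng.standard_normal())
    if D is None:
        D = _sample_flight(space.d, flight_probs, rng)
    x_i = pop.positions[i]
    v = space.clamp(x_i + b * D * x_i)
    fv = _check_fitness(objective(v), v)
    if fv < pop.fitness[i]:
        pop.positions[i] = v
        pop.fitness[i] = fv
        update_visit_table(vt, i, None, replaced_source=i)
    else:
        update_visit_table(vt, i, None)


def migration_step(
    pop: Population,
    vt: np.ndarray,
    objective,
    space: SearchSpace,
    rng: np.random.Generator,
) -> int:
    """Replace the worst source with a fresh uniform draw; returns its index."""
    w = int(np.argmax(pop.fitness))
    x_new = space.uniform(rng)
    pop.positions[w] = x_new
    pop.fitness[w] = _check_fitness(objective(x_new), x_new)
    update_visit_table(vt, w, None, replaced_source=w)
    return w


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray  # best-so-far fitness, length max_iters + 1
    n_evals: int = 0


def optimize(objective, space: SearchSpace, config: AHBAConfig) -> OptimizeResult:
    """Run the full algorithm; elitist best-so-far trace is non-increasing."""
    rng = np.random.default_rng(config.seed)
    period = config.migration_period if config.migration_period is not None else 2 * config.n

    n_evals = 0

    def counted(x):
        nonlocal n_evals
        n_evals += 1
        return objective(x)

    pop = initialize_population(space, config.n, counted, rng)
    vt = init_visit_table(config.n)

    best_i = pop.best_index
    best_x = pop.positions[best_i].copy()
    best_f = float(pop.fitness[best_i])
    trace = [best_f]

    for it in range(1, config.max_iters + 1):
        for i in range(config.n):
            if rng.uniform() < config.guided_prob:
                guided_foraging_step(pop, vt, i, counted, space, rng, config.flight_probs)
            else:
                territorial_foraging_step(pop, vt, i, counted, space, rng, config.flight_probs)
        if it % period == 0:
            migration_step(pop, vt, counted, space, rng)
        cur = pop.best_index
        if pop.fitness[cur] < best_f:
            best_f = float(pop.fitness[cur])
            best_x = pop.positions[cur].copy()
        trace.append(best_f)

    return OptimizeResult(x=best_x, fun=best_f, trace=np.array(trace), n_evals=n_evals)


def random_search(objective, space: SearchSpace, n_evals: int, seed: int) -> OptimizeResult:
    """Uniform random search baseline with an identical evaluation budget."""
    rng = np.random.default_rng(seed)
    best_x = None
    best_f = math.inf
    trace = []
    for _ in range(n_evals):
        x = space.uniform(rng)
        f = _check_fitness(objective(x), x)
        if f < best_f:
            best_f, best_x = f, x
        trace.append(best_f)
    return OptimizeResult(x=best_x, fun=best_f, trace=np.array(trace), n_evals=n_evals)
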