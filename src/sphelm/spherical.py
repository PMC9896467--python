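"""Spherical-search (SS) global optimization over a box.

A population-based optimizer for bounded continuous minimization.  Each
individual x_i proposes a trial point

    y_i = x_i + c_i * (m_i @ z_i)

where z_i is a search direction built from other population members
("towards-rand" for the better half of the population, "towards-best"
— attracted to a random member of the top-p fraction — for the worse
half), m_i = A' diag(b_i) A is a random orthogonal projection of rank
rank_i (so the step lies on a lower-dimensional spherical neighborhood
of x_i), and c_i is a step size.  Greedy selection keeps the trial iff
it does not worsen the objective.

The two control parameters rank_i and c_i are adapted by
success-history-based parameter adaptation (SHPA): a cyclic memory of H
cells stores weighted Lehmer means of the (rank/D, c) values that
produced improvements, and new values are drawn as
rank_i ~ Binomial(D, mem_rank) and c_i ~ Cauchy(mem_step, 0.1)
(resampled while <= 0, truncated at 1).  The population shrinks from
``pop_init`` to ``pop_min`` over the evaluation budget, dropping the
worst-ranked members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "SSConfig",
    "SSState",
    "SSResult",
    "init_population",
    "make_projection",
    "sample_control_params",
    "assign_directions",
    "trial_solution",
    "greedy_select",
    "update_memory",
    "population_schedule",
    "reduce_population",
    "optimize",
    "BENCHMARKS",
]


@dataclass
class SSConfig:
    """Spherical-search settings.

    Defaults follow the published configuration: budget 10,000
    evaluations, population 100 shrinking to 4, pbest fraction 0.11,
    success-history size 5, memory initialized at rank probability 0.5
    and step size 0.7.
    """

    nfes_max: int = 10_000
    pop_init: int = 100
    pop_min: int = 4
    pbest_rate: float = 0.11
    memory_size: int = 5
    init_rank_prob: float = 0.5
    init_step: float = 0.7
    lower: float | np.ndarray = -1.0
    upper: float | np.ndarray = 1.0
    seed: int = 0
    reduction: str = "linear"

    def __post_init__(self) -> None:
        if not (0.0 < self.pbest_rate <= 1.0):
            raise ValueError("pbest_rate must be in (0, 1]")
        if self.pop_min < 4:
            raise ValueError("pop_min must be at least 4 (distinct index draws)")
        if self.pop_init < self.pop_min:
            raise ValueError("pop_init must be >= pop_min")
        if self.memory_size < 1:
            raise ValueError("memory_size must be positive")
        if self.reduction not in ("linear", "exponential"):
            raise ValueError("reduction must be 'linear' or 'exponential'")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (dim,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (dim,)).copy()
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if (lower > upper).any():
            raise ValueError("lower bound exceeds upper bound")
        return lower, upper


@dataclass
class SSState:
    """Population, fitnesses, SHPA memory and evaluation counter."""

    population: np.ndarray  # (N, D)
    fitnesses: np.ndarray  # (N,)
    memory: np.ndarray  # (2, H): row 0 rank probability, row 1 step size
    memory_cursor: int = 0
    nfes: int = 0
    best_x: np.ndarray | None = None
    best_f: float = math.inf

    @property
    def size(self) -> int:
        return self.population.shape[0]

    @property
    def dim(self) -> int:
        return self.population.shape[1]

    def track_best(self) -> None:
        i = int(np.argmin(self.fitnesses))
        if self.fitnesses[i] <= self.best_f:
            self.best_f = float(self.fitnesses[i])
            self.best_x = self.population[i].copy()


@dataclass
class SSResult:
    best_x: np.ndarray
    best_f: float
    nfes: int
    trace: pd.DataFrame
    state: SSState = field(repr=False, default=None)  # type: ignore[assignment]


def _safe_objective(objective: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    def wrapped(x: np.ndarray) -> float:
        value = float(objective(x))
        if not math.isfinite(value):
            warnings.warn("objective returned a non-finite value; treated as +inf")
            return math.inf
        return value

    return wrapped


def init_population(
    objective: Callable[[np.ndarray], float],
    dim: int,
    config: SSConfig,
    rng: np.random.Generator,
) -> SSState:
    """Uniform initial population in (lower, upper], evaluated."""
    lower, upper = config.bounds(dim)
    # 1 - random() lies in (0, 1]
    u = 1.0 - rng.random((config.pop_init, dim))
    population = (upper - lower) * u + lower
    f = _safe_objective(objective)
    fitnesses = np.array([f(x) for x in population])
    memory = np.vstack(
        [
            np.full(config.memory_size, config.init_rank_prob),
            np.full(config.memory_size, config.init_step),
        ]
    )
    state = SSState(population, fitnesses, memory, nfes=config.pop_init)
    state.track_best()
    return state


def _random_orthogonal(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Orthogonalize a standard-normal matrix (QR with sign fix)."""
    M = rng.standard_normal((dim, dim))
    Q, R = np.linalg.qr(M)
    return Q * np.sign(np.diag(R))


def make_projection(dim: int, rank: int, rng: np.random.Generator, A: np.ndarray | None = None) -> np.ndarray:
    """Random rank-``rank`` orthogonal projection m = A' diag(b) A.

    ``rank`` must lie in [1, dim - 1] for optimization use (``rank ==
    dim`` yields the identity and is allowed only for direct calls).
    The result is symmetric, idempotent, with trace equal to ``rank``.
    """
    if not (1 <= rank <= dim):
        raise ValueError(f"rank {rank} out of range [1, {dim}]")
    if A is None:
        A = _random_orthogonal(dim, rng)
    b = np.zeros(dim)
    b[rng.choice(dim, size=rank, replace=False)] = 1.0
    return A.T @ (b[:, None] * A)


def sample_control_params(
    state: SSState, config: SSConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (rank_i, c_i) for each individual from the SHPA memory.

    Each individual picks a memory column uniformly; rank_i ~
    Binomial(D, mem_rank) clamped to [1, D-1]; c_i ~ Cauchy(mem_step,
    0.1), resampled while <= 0 and truncated at 1.
    """
    N, D = state.size, state.dim
    cols = rng.integers(0, config.memory_size, size=N)
    rank_p = state.memory[0, cols]
    ranks = rng.binomial(D, rank_p)
    ranks = np.clip(ranks, 1, max(D - 1, 1))
    locs = state.memory[1, cols]
    cs = locs + 0.1 * rng.standard_cauchy(N)
    for _ in range(100):
        bad = cs <= 0.0
        if not bad.any():
            break
        cs[bad] = locs[bad] + 0.1 * rng.standard_cauchy(int(bad.sum()))
    np.clip(cs, 1e-8, 1.0, out=cs)
    return ranks.astype(int), cs


def assign_directions(fitnesses: np.ndarray) -> np.ndarray:
    """Boolean mask: True = towards-rand (better half), False = towards-best.

    The better half by fitness searches towards-rand; the worse half —
    including the median when N is odd — is pulled towards-best.  Ties
    split by index order (stable argsort), so the result is
    deterministic.
    """
    N = len(fitnesses)
    order = np.argsort(fitnesses, kind="stable")
    mask = np.zeros(N, dtype=bool)
    mask[order[: N // 2]] = True
    return mask


def _distinct_indices(N: int, i: int, count: int, rng: np.random.Generator) -> np.ndarray:
    pool = np.delete(np.arange(N), i)
    return rng.choice(pool, size=count, replace=False)


def _propose(
    population: np.ndarray,
    fitnesses: np.ndarray,
    i: int,
    c_i: float,
    m_i: np.ndarray,
    towards_rand: bool,
    pbest_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unrepaired trial point y_i = x_i + c_i * (m_i @ z_i)."""
    N = population.shape[0]
    if N < 4:
        raise ValueError("population too small to draw three distinct partners")
    x_i = population[i]
    p, q, r = _distinct_indices(N, i, 3, rng)
    if towards_rand:
        attractor = population[p]
    else:
        n_top = max(1, math.ceil(pbest_rate * N))
        top = np.argsort(fitnesses, kind="stable")[:n_top]
        attractor = population[rng.choice(top)]
    z = attractor + population[q] - population[r] - x_i
    return x_i + c_i * (m_i @ z)


def repair_bounds(
    y: np.ndarray, x: np.ndarray, lower: np.ndarray, upper: np.ndarray
) -> np.ndarray:
    """Midpoint reflection: a violated coordinate moves to the midpoint
    between its parent value and the violated bound."""
    y = y.copy()
    low = y < lower
    y[low] = (x[low] + lower[low]) / 2.0
    high = y > upper
    y[high] = (x[high] + upper[high]) / 2.0
    return y


def trial_solution(
    state: SSState,
    i: int,
    c_i: float,
    m_i: np.ndarray,
    towards_rand: bool,
    config: SSConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bound-repaired trial point for individual ``i``."""
    y = _propose(
        state.population, state.fitnesses, i, c_i, m_i, towards_rand,
        config.pbest_rate, rng,
    )
    lower, upper = config.bounds(state.dim)
    return repair_bounds(y, state.population[i], lower, upper)


def greedy_select(
    state: SSState,
    trials: np.ndarray,
    trial_fitnesses: np.ndarray,
    ranks: np.ndarray,
    cs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Replace parents whose trial is no worse; record successes.

    Returns the success records (ranks, step sizes, improvement
    weights) for the SHPA memory update.  Acceptance uses <=, so an
    equal-fitness trial replaces its parent (with improvement weight 0).
    """
    accepted = trial_fitnesses <= state.fitnesses[: len(trial_fitnesses)]
    idx = np.nonzero(accepted)[0]
    improvements = state.fitnesses[idx] - trial_fitnesses[idx]
    state.population[idx] = trials[idx]
    state.fitnesses[idx] = trial_fitnesses[idx]
    state.track_best()
    return {
        "ranks": ranks[idx].astype(float),
        "cs": cs[idx].astype(float),
        "weights": improvements.astype(float),
    }


def _lehmer(values: np.ndarray, weights: np.ndarray) -> float | None:
    denom = float(np.sum(weights * values))
    if denom <= 0.0:
        return None
    return float(np.sum(weights * values**2) / denom)


def update_memory(state: SSState, successes: dict[str, np.ndarray]) -> None:
    """Overwrite the cursor cell with weighted Lehmer means of successes.

    Ranks enter as probabilities rank/D.  Weights are the normalized
    fitness improvements; if no trial strictly improved (all weights 0)
    or there were no successes, the memory is left unchanged and the
    cursor does not advance.
    """
    ranks, cs, weights = successes["ranks"], successes["cs"], successes["weights"]
    if len(weights) == 0:
        return
    # an infinite parent fitness gives an infinite improvement; cap it so
    # the weight normalization stays finite
    finite = np.isfinite(weights)
    if not finite.all():
        cap = weights[finite].max() if finite.any() else 1.0
        weights = np.where(finite, weights, max(cap, 1.0))
    if weights.sum() <= 0.0:
        return
    w = weights / weights.sum()
    new_rank = _lehmer(ranks / state.dim, w)
    new_step = _lehmer(cs, w)
    if new_rank is not None:
        state.memory[0, state.memory_cursor] = min(new_rank, 1.0)
    if new_step is not None:
        state.memory[1, state.memory_cursor] = min(new_step, 1.0)
    state.memory_cursor = (state.memory_cursor + 1) % state.memory.shape[1]


def population_schedule(nfes: int, config: SSConfig) -> int:
    """Target population size after ``nfes`` evaluations.

    Interpolates from ``pop_init`` at 0 to ``pop_min`` at ``nfes_max``
    (linear by default, exponential optional); clamped at pop_min.
    """
    t = min(max(nfes / config.nfes_max, 0.0), 1.0)
    if config.reduction == "linear":
        target = round(config.pop_init + (config.pop_min - config.pop_init) * t)
    else:
        target = round(config.pop_init * (config.pop_min / config.pop_init) ** t)
    return max(config.pop_min, int(target))


def reduce_population(state: SSState, config: SSConfig) -> None:
    """Drop the worst-ranked individuals down to the scheduled size."""
    target = population_schedule(state.nfes, config)
    if target < state.size:
        keep = np.argsort(state.fitnesses, kind="stable")[:target]
        keep.sort()  # preserve relative order of survivors
        state.population = state.population[keep]
        state.fitnesses = state.fitnesses[keep]


def optimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    config: SSConfig | None = None,
) -> SSResult:
    """Minimize ``objective`` over the configured box.

    Loops sample -> trial -> greedy select -> memory update -> reduce
    until the evaluation budget is exhausted.  Fully reproducible from
    ``config.seed``.  A maximization problem is handled by passing the
    negated objective.
    """
    config = config or SSConfig()
    rng = np.random.default_rng(config.seed)
    f = _safe_objective(objective)
    state = init_population(f, dim, config, rng)
    lower, upper = config.bounds(dim)
    records = [(0, state.nfes, state.size, state.best_f)]
    iteration = 0

    while state.nfes < config.nfes_max:
        iteration += 1
        N = state.size
        ranks, cs = sample_control_params(state, config, rng)
        directions = assign_directions(state.fitnesses)
        A = _random_orthogonal(dim, rng)

        # Batched projection: for each i, m_i z_i = A' diag(b_i) A z_i.
        zs = np.empty((N, dim))
        for i in range(N):
            x_i = state.population[i]
            p, q, r = _distinct_indices(N, i, 3, rng)
            if directions[i]:
                attractor = state.population[p]
            else:
                n_top = max(1, math.ceil(config.pbest_rate * N))
                top = np.argsort(state.fitnesses, kind="stable")[:n_top]
                attractor = state.population[rng.choice(top)]
            zs[i] = attractor + state.population[q] - state.population[r] - x_i
        masks = np.zeros((N, dim))
        for i in range(N):
            masks[i, rng.choice(dim, size=ranks[i], replace=False)] = 1.0
        steps = ((zs @ A.T) * masks) @ A  # row i = m_i @ z_i
        trials = state.population + cs[:, None] * steps
        for i in range(N):
            trials[i] = repair_bounds(trials[i], state.population[i], lower, upper)

        n_eval = min(N, config.nfes_max - state.nfes)
        trial_f = np.array([f(y) for y in trials[:n_eval]])
        successes = greedy_select(state, trials[:n_eval], trial_f, ranks[:n_eval], cs[:n_eval])
        update_memory(state, successes)
        state.nfes += n_eval
        reduce_population(state, config)
        records.append((iteration, state.nfes, state.size, state.best_f))

    trace = pd.DataFrame(records, columns=["iteration", "nfes", "pop_size", "best_value"])
    return SSResult(state.best_x.copy(), state.best_f, state.nfes, trace, state)


# -- benchmark objectives ---------------------------------------------

def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def rastrigin(x: np.ndarray) -> float:
    return float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2))


BENCHMARKS = {"sphere": sphere, "rastrigin": rastrigin, "rosenbrock": rosenbrock}
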