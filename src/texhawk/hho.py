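"""Harris Hawks Optimization: a population metaheuristic for continuous minimization.

The population of "hawks" chases the best solution found so far (the
"rabbit").  A decaying escape energy E = 2 E0 (1 - t/T) switches behavior:
|E| >= 1 triggers randomized exploration, smaller |E| triggers exploitation
moves (soft besiege, hard besiege, or rapid dives toward the rabbit), with the
escape step J ~ U[0, 2] scaling how far the prey is assumed to jump.  Dive
candidates are accepted greedily, so the best-so-far cost is non-increasing.

The exploration and besiege updates follow the commonly printed update rules;
the Levy-flight progressive-dive refinement of the original formulation is
off by default and available via ``levy_dives``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "HHOParams",
    "ConvergenceHistory",
    "HHOResult",
    "escape_energy",
    "mean_position",
    "exploration_step",
    "soft_besiege",
    "hard_besiege",
    "rapid_dive_step",
    "hho_minimize",
    "random_search_minimize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HHOParams:
    """Optimizer settings; defaults follow the usual published configuration
    (population 30, 100 iterations, energy and escape-step ranges topping at 2)."""

    n_hawks: int = 30
    n_iter: int = 100
    lb: float | Sequence[float] = 0.0
    ub: float | Sequence[float] = 1.0
    e0_fixed: float | None = None  # fix E0 instead of resampling in U(-1, 1)
    levy_dives: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hawks < 2:
            raise ValueError("n_hawks must be >= 2")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0 (0 evaluates the initial population only)")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lb, dtype=np.float64), (dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=np.float64), (dim,)).copy()
        if np.any(lb >= ub):
            raise ValueError("lower bounds must be strictly below upper bounds")
        return lb, ub


@dataclass
class ConvergenceHistory:
    """Per-iteration trace: best cost so far, population mean cost, mean |E|."""

    best_cost: list[float] = field(default_factory=list)
    mean_cost: list[float] = field(default_factory=list)
    mean_abs_energy: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def record(self, best: float, mean: float, energy: float) -> None:
        if self.best_cost and best > self.best_cost[-1] + 0.0:
            raise AssertionError("best-so-far cost increased")
        self.best_cost.append(float(best))
        self.mean_cost.append(float(mean))
        self.mean_abs_energy.append(float(energy))

    def to_rows(self) -> list[dict]:
        return [
            {"iteration": i, "best_cost": b, "mean_cost": m, "mean_abs_energy": e}
            for i, (b, m, e) in enumerate(zip(self.best_cost, self.mean_cost, self.mean_abs_energy))
        ]


@dataclass(frozen=True)
class HHOResult:
    best_position: np.ndarray
    best_cost: float
    history: ConvergenceHistory


def escape_energy(e0: float, t: int, n_iter: int) -> float:
    """Escape energy E = 2 E0 (1 - t/T); decays linearly to exactly 0 at t = T."""
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if not 0 <= t <= n_iter:
        raise ValueError(f"iteration {t} outside [0, {n_iter}]")
    return 2.0 * e0 * (1.0 - t / n_iter)


def mean_position(population: np.ndarray) -> np.ndarray:
    """Centroid of the population, one value per dimension."""
    pop = np.asarray(population, dtype=np.float64)
    if pop.size == 0:
        raise ValueError("population must be non-empty")
    return pop.mean(axis=0)


def exploration_step(
    x: np.ndarray,
    x_rand: np.ndarray,
    x_rabbit: np.ndarray,
    x_mean: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomized perch relocation used while |E| >= 1.

    With probability 1/2 the hawk perches relative to a random flock member,
    otherwise relative to the rabbit, the flock centroid and the search bounds.
    """
    q = rng.random()
    r1, r2, r3, r4 = rng.random(4)
    if q >= 0.5:
        return x_rand - r1 * np.abs(x_rand - 2.0 * r2 * x)
    return (x_rabbit - x_mean) - r3 * (lb + r4 * (ub - lb))


def soft_besiege(x: np.ndarray, x_rabbit: np.ndarray, e: float, j: float) -> np.ndarray:
    """Soft besiege (|E| >= 0.5): X' = dX - E |J X_rabbit - X| with dX = X_rabbit - X."""
    dx = x_rabbit - x
    return dx - e * np.abs(j * x_rabbit - x)


def hard_besiege(x: np.ndarray, x_rabbit: np.ndarray, e: float) -> np.ndarray:
    """Hard besiege (|E| < 0.5): X' = X_rabbit - E |X_rabbit - X|."""
    return x_rabbit - e * np.abs(x_rabbit - x)


def rapid_dive_step(x_rabbit: np.ndarray, x_mean: np.ndarray, e: float, j: float) -> np.ndarray:
    """Rapid-dive candidate: X' = X_rabbit - E |J X_rabbit - X_mean|.

    Callers accept the candidate only if it improves the hawk's cost.
    """
    return x_rabbit - e * np.abs(j * x_rabbit - x_mean)


def _levy(rng: np.random.Generator, dim: int, beta: float = 1.5) -> np.ndarray:
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    u = rng.standard_normal(dim) * sigma
    v = rng.standard_normal(dim)
    return 0.01 * u / np.abs(v) ** (1 / beta)


def hho_minimize(cost_fn: Callable[[np.ndarray], float], dim: int, params: HHOParams) -> HHOResult:
    """Minimize ``cost_fn`` over ``[lb, ub]^dim``; reproducible under ``params.seed``.

    Per iteration, per hawk: sample E0 (or use the fixed value) and the escape
    energy E; |E| >= 1 dispatches exploration, otherwise r >= 0.5 dispatches
    soft (|E| >= 0.5) or hard (|E| < 0.5) besiege, and r < 0.5 a rapid dive
    accepted only on improvement.  Positions are clamped to the bounds before
    evaluation; non-finite costs reject the candidate.
    """
    lb, ub = params.bounds(dim)
    rng = np.random.default_rng(params.seed)
    history = ConvergenceHistory()

    def evaluate(x: np.ndarray) -> float:
        history.n_evaluations += 1
        return float(cost_fn(x))

    pop = lb + rng.random((params.n_hawks, dim)) * (ub - lb)
    costs = np.array([evaluate(x) for x in pop])
    bad = ~np.isfinite(costs)
    if bad.any():
        logger.warning("non-finite cost for %d initial hawks; treated as +inf", int(bad.sum()))
        costs[bad] = np.inf
    best_idx = int(np.argmin(costs))
    best_x, best_cost = pop[best_idx].copy(), float(costs[best_idx])
    history.record(best_cost, float(np.mean(costs[np.isfinite(costs)])), 2.0)

    for t in range(1, params.n_iter + 1):
        x_mean = mean_position(pop)
        abs_e_sum = 0.0
        for i in range(params.n_hawks):
            e0 = params.e0_fixed if params.e0_fixed is not None else rng.uniform(-1.0, 1.0)
            e = escape_energy(e0, t, params.n_iter)
            abs_e_sum += abs(e)
            j = 2.0 * (1.0 - rng.random())
            x = pop[i]
            if abs(e) >= 1.0:
                k = int(rng.integers(params.n_hawks))
                new_x = exploration_step(x, pop[k], best_x, x_mean, lb, ub, rng)
                accept_greedy = False
            else:
                r = rng.random()
                if r >= 0.5:
                    new_x = soft_besiege(x, best_x, e, j) if abs(e) >= 0.5 else hard_besiege(x, best_x, e)
                    accept_greedy = False
                else:
                    # rapid-dive variants: the soft form dives relative to the
                    # hawk's own position, the hard form relative to the centroid
                    anchor = x if abs(e) >= 0.5 else x_mean
                    new_x = rapid_dive_step(best_x, anchor, e, j)
                    accept_greedy = True
            new_x = np.clip(new_x, lb, ub)
            new_cost = evaluate(new_x)
            if not np.isfinite(new_cost):
                logger.warning("non-finite cost at iteration %d, hawk %d; candidate rejected", t, i)
                continue
            if accept_greedy and new_cost >= costs[i] and params.levy_dives:
                # second-chance dive: Levy-perturbed candidate, still greedy
                z = np.clip(new_x + rng.random(dim) * _levy(rng, dim), lb, ub)
                z_cost = evaluate(z)
                if np.isfinite(z_cost) and z_cost < costs[i]:
                    new_x, new_cost = z, z_cost
            if accept_greedy and new_cost >= costs[i]:
                continue
            pop[i], costs[i] = new_x, new_cost
            if new_cost < best_cost:
                best_x, best_cost = new_x.copy(), float(new_cost)
        history.record(best_cost, float(np.mean(costs[np.isfinite(costs)])), abs_e_sum / params.n_hawks)

    return HHOResult(best_position=best_x, best_cost=best_cost, history=history)


def random_search_minimize(
    cost_fn: Callable[[np.ndarray], float], dim: int, params: HHOParams
) -> HHOResult:
    """Uniform random search with the same evaluation budget; testing baseline."""
    lb, ub = params.bounds(dim)
    rng = np.random.default_rng(params.seed)
    history = ConvergenceHistory()
    budget = params.n_hawks * (params.n_iter + 1)
    best_x, best_cost = None, np.inf
    for _ in range(budget):
        x = lb + rng.random(dim) * (ub - lb)
        c = float(cost_fn(x))
        history.n_evaluations += 1
        if c < best_cost:
            best_x, best_cost = x, c
    history.record(best_cost, best_cost, 0.0)
    return HHOResult(best_position=best_x, best_cost=float(best_cost), history=history)
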