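"""Whale optimization, grey wolf optimization and the multi-strategy
WOA-GWO hybrid.

All three optimizers minimize a continuous objective over a box.  The
hybrid splits the population into a whale subpopulation (global
exploration: shrinking encircling, random search, and a spiral update
guided jointly by the global best and the wolf pack's alpha) and a wolf
subpopulation (local exploitation: alpha/beta/delta hierarchical updates
with fitness-adaptive leader weights), coupled by an elite-exchange step
each generation.  Four additional strategies sharpen the search: logistic
chaotic initialization, a nonlinear convergence factor, greedy (improve-
only) acceptance, and periodic random perturbation of the worst
individuals.

Binary feature-selection problems are handled by searching the continuous
box and thresholding positions (``binarize_position``) inside the
objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace", "OptimizerConfig", "OptimizationResult",
    "chaotic_init", "convergence_factor", "binarize_position",
    "population_diversity", "reflect_bounds", "encircle_update",
    "spiral_update", "random_search_update", "gwo_candidates",
    "leader_weights", "hybrid_spiral_update", "perturb", "run_optimizer",
]


@dataclass
class SearchSpace:
    """A box-bounded continuous search problem.

    ``objective`` maps a position vector to a scalar.  With
    ``maximize=True`` the value is negated internally, so the optimizer
    always minimizes; curves and ``best_fitness`` are reported on the
    internal (minimized) scale and ``OptimizationResult.best_value``
    restores the user's scale.
    """

    dim: int
    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]
    maximize: bool = False

    def __post_init__(self) -> None:
        self.lower = np.broadcast_to(np.asarray(self.lower, float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, float), (self.dim,)).copy()
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def evaluate(self, x: np.ndarray) -> float:
        v = float(self.objective(x))
        return -v if self.maximize else v

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.upper - self.lower))


@dataclass
class OptimizerConfig:
    """Tunables shared by the three optimizers.

    ``convergence_mode`` selects how the control parameter ``a`` decays in
    the hybrid: ``"printed_eq45"`` is the nonlinear factor
    a = 2 - 2 (t/T)(1 - t/T), which dips to 1.5 mid-run and returns to 2 —
    it keeps exploration pressure high throughout and relies on greedy
    acceptance for convergence; ``"linear"`` is the classic 2(1 - t/T)
    decay.  Standalone WOA/GWO always use the linear decay.
    """

    pop_size: int = 30
    max_iter: int = 300
    seed: int = 0
    b: float = 1.0
    convergence_mode: str = "printed_eq45"
    chaotic_map: str = "logistic"
    perturb_period: int = 25
    perturb_fraction: float = 0.1
    whale_fraction_schedule: tuple[float, float] = (0.7, 0.3)
    elite_exchange: bool = True
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be at least 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if not (0 < self.perturb_fraction <= 1):
            raise ValueError("perturb_fraction must be in (0, 1]")
        lo, hi = self.whale_fraction_schedule
        if not (0 <= lo <= 1 and 0 <= hi <= 1):
            raise ValueError("whale_fraction_schedule values must lie in [0, 1]")


@dataclass
class OptimizationResult:
    """Outcome of one optimizer run.

    ``convergence_curve`` holds the best-so-far objective (internal,
    minimized scale) after each of the T iterations and is therefore
    monotone non-increasing; ``diversity_curve`` the normalized population
    diversity at the same instants.
    """

    best_position: np.ndarray
    best_fitness: float
    convergence_curve: np.ndarray
    diversity_curve: np.ndarray
    evaluations: int
    seed: int
    algorithm: str
    maximize: bool = False

    @property
    def best_value(self) -> float:
        """Best objective on the user's scale (undoes internal negation)."""
        return -self.best_fitness if self.maximize else self.best_fitness

    def plot_convergence(self, ax=None):  # pragma: no cover - plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.convergence_curve) + 1),
                self.convergence_curve)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best objective")
        ax.set_title(f"{self.algorithm} convergence")
        return ax


# ---------------------------------------------------------------------------
# primitives

_LOGISTIC_FIXED_POINTS = (0.25, 0.5, 0.75)


def logistic_iterates(c0: float, n: int) -> np.ndarray:
    """First ``n`` iterates of the logistic map c -> 4 c (1 - c)."""
    out = np.empty(n)
    c = c0
    for i in range(n):
        c = 4.0 * c * (1.0 - c)
        out[i] = c
    return out


def chaotic_init(pop_size: int, space: SearchSpace,
                 seed: int | np.random.Generator = 0,
                 chaotic_map: str = "logistic") -> np.ndarray:
    """Chaotic-map population initialization.

    One logistic chain c_{k+1} = 4 c_k (1 - c_k) per dimension, started
    from a seeded c_0 in (0, 1) away from the map's fixed/periodic points
    {0.25, 0.5, 0.75}, affinely mapped into the box.  The tent map
    c_{k+1} = 2 min(c, 1-c) is available behind ``chaotic_map="tent"``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.empty((pop_size, space.dim))
    span = space.upper - space.lower
    for d in range(space.dim):
        c = rng.uniform(0.05, 0.95)
        while any(abs(c - fp) < 1e-3 for fp in _LOGISTIC_FIXED_POINTS):
            c = rng.uniform(0.05, 0.95)
        for i in range(pop_size):
            if chaotic_map == "logistic":
                c = 4.0 * c * (1.0 - c)
            elif chaotic_map == "tent":
                c = 2.0 * min(c, 1.0 - c)
                if c in (0.0, 1.0):
                    c = rng.uniform(0.05, 0.95)
            else:
                raise ValueError(f"unknown chaotic map {chaotic_map!r}")
            pos[i, d] = space.lower[d] + c * span[d]
    return pos


def convergence_factor(t: int, T: int, mode: str = "printed_eq45") -> float:
    """Control parameter ``a`` at iteration t of T.

    ``printed_eq45``: a = 2 - 2 (t/T)(1 - t/T) (nonlinear; in [1.5, 2]).
    ``linear``: a = 2 (1 - t/T).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    frac = t / T
    if mode == "printed_eq45":
        return 2.0 - 2.0 * frac * (1.0 - frac)
    if mode == "linear":
        return 2.0 * (1.0 - frac)
    raise ValueError(f"unknown convergence mode {mode!r}")


def binarize_position(x: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Binary mask: 1 where the coordinate strictly exceeds the threshold."""
    return (np.asarray(x, dtype=float) > threshold).astype(int)


def population_diversity(positions: np.ndarray, space: SearchSpace) -> float:
    """Mean pairwise Euclidean distance normalized by the box diagonal."""
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise ValueError("diversity needs at least 2 individuals")
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    iu = np.triu_indices(positions.shape[0], k=1)
    return float(np.sqrt(d2[iu]).mean() / space.diagonal)


def reflect_bounds(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Fold out-of-bounds coordinates back into the box by reflection."""
    span = upper - lower
    y = np.mod(np.asarray(x, float) - lower, 2.0 * span)
    return lower + np.where(y > span, 2.0 * span - y, y)


def encircle_update(best: np.ndarray, x: np.ndarray, A: float | np.ndarray,
                    C: float | np.ndarray) -> np.ndarray:
    """Shrinking-encircling move toward the best position."""
    return best - A * np.abs(C * best - x)


def spiral_update(best: np.ndarray, x: np.ndarray, b: float, l: float) -> np.ndarray:
    """Logarithmic spiral move around the best position."""
    return np.abs(best - x) * math.exp(b * l) * math.cos(2.0 * math.pi * l) + best


def random_search_update(x_rand: np.ndarray, x: np.ndarray, A: float | np.ndarray,
                         C: float | np.ndarray) -> np.ndarray:
    """Exploration move referenced to a random individual."""
    return x_rand - A * np.abs(C * x_rand - x)


def gwo_candidates(x: np.ndarray, leaders: Sequence[np.ndarray], a: float,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Candidate positions generated by each leader (alpha, beta, delta)."""
    out = []
    for leader in leaders:
        r1 = rng.random(x.size)
        r2 = rng.random(x.size)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        out.append(leader - A * np.abs(C * leader - x))
    return out


def leader_weights(f_leaders: Sequence[float], f_best: float,
                   f_worst: float, normalize: bool = True) -> np.ndarray:
    """Fitness-adaptive leader weights w_i = (f_worst - f_i)/(f_worst - f_best).

    Degenerate populations (f_worst == f_best) fall back to equal weights.
    With ``normalize=True`` (the form used in the position update) the
    vector is rescaled to sum to 1.
    """
    if f_worst == f_best:
        return np.full(len(f_leaders), 1.0 / len(f_leaders))
    w = (f_worst - np.asarray(f_leaders, float)) / (f_worst - f_best)
    if not normalize:
        return w
    total = w.sum()
    if total <= 0:
        return np.full(len(f_leaders), 1.0 / len(f_leaders))
    return w / total


def hybrid_spiral_update(x: np.ndarray, best: np.ndarray, alpha: np.ndarray,
                         C: float | np.ndarray, b: float, l: float) -> np.ndarray:
    """Spiral move anchored at the whale-best / alpha-wolf midpoint.

    X(t+1) = (X_best + X_alpha)/2 + |C o X_best - X| e^{bl} cos(2 pi l),
    with elementwise absolute value — the whale spiral with alpha-wolf
    guidance added for directionality.
    """
    mid = 0.5 * (best + alpha)
    return mid + np.abs(C * best - x) * math.exp(b * l) * math.cos(2.0 * math.pi * l)


def perturb(positions: np.ndarray, fitness: np.ndarray, space: SearchSpace,
            rng: np.random.Generator, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Redraw the worst ``ceil(fraction * pop)`` individuals uniformly.

    The single best individual is never perturbed (elitism).  Returns the
    updated positions and the indices that were redrawn (their fitness
    must be re-evaluated by the caller).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    pop = positions.shape[0]
    n_redraw = min(math.ceil(fraction * pop), pop - 1)
    order = np.argsort(fitness, kind="stable")  # ascending: best first
    victims = order[pop - n_redraw:]
    positions = positions.copy()
    positions[victims] = rng.uniform(space.lower, space.upper,
                                     size=(n_redraw, space.dim))
    return positions, victims


# ---------------------------------------------------------------------------
# drivers


class _State:
    """Mutable population state shared by the drivers."""

    def __init__(self, space: SearchSpace, positions: np.ndarray):
        self.space = space
        self.positions = positions
        self.fitness = np.array([space.evaluate(p) for p in positions])
        self.evaluations = positions.shape[0]
        ibest = int(np.argmin(self.fitness))
        self.best_position = positions[ibest].copy()
        self.best_fitness = float(self.fitness[ibest])

    def evaluate(self, x: np.ndarray) -> float:
        self.evaluations += 1
        return self.space.evaluate(x)

    def refresh_best(self) -> None:
        ibest = int(np.argmin(self.fitness))
        if self.fitness[ibest] < self.best_fitness:
            self.best_fitness = float(self.fitness[ibest])
            self.best_position = self.positions[ibest].copy()

    def leaders(self, idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(positions, fitnesses) of the top-3 individuals of a subset."""
        if idx is None:
            idx = np.arange(self.positions.shape[0])
        order = idx[np.argsort(self.fitness[idx], kind="stable")][:3]
        if len(order) < 3:  # tiny subpopulation: repeat the best
            order = np.concatenate([order, np.repeat(order[:1], 3 - len(order))])
        return self.positions[order].copy(), self.fitness[order].copy()


def _woa_move(state: _State, i: int, a: float, b: float,
              rng: np.random.Generator) -> np.ndarray:
    r1, r2 = rng.random(2)
    A = 2.0 * a * r1 - a
    C = 2.0 * r2
    p = rng.random()
    l = rng.uniform(-1.0, 1.0)
    x = state.positions[i]
    if p < 0.5:
        if abs(A) < 1:
            return encircle_update(state.best_position, x, A, C)
        j = int(rng.integers(state.positions.shape[0]))
        return random_search_update(state.positions[j], x, A, C)
    return spiral_update(state.best_position, x, b, l)


def _run_woa(space: SearchSpace, config: OptimizerConfig) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(space.lower, space.upper,
                            size=(config.pop_size, space.dim))
    state = _State(space, positions)
    T = config.max_iter
    curve = np.empty(T)
    div = np.empty(T)
    for t in range(T):
        a = convergence_factor(t, T, "linear")
        for i in range(config.pop_size):
            x_new = reflect_bounds(_woa_move(state, i, a, config.b, rng),
                                   space.lower, space.upper)
            state.positions[i] = x_new
            state.fitness[i] = state.evaluate(x_new)
        state.refresh_best()
        curve[t] = state.best_fitness
        div[t] = population_diversity(state.positions, space)
    return OptimizationResult(state.best_position, state.best_fitness, curve,
                              div, state.evaluations, config.seed, "woa",
                              space.maximize)


def _run_gwo(space: SearchSpace, config: OptimizerConfig,
             weighted: bool = False) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(space.lower, space.upper,
                            size=(config.pop_size, space.dim))
    state = _State(space, positions)
    T = config.max_iter
    curve = np.empty(T)
    div = np.empty(T)
    for t in range(T):
        a = convergence_factor(t, T, "linear")
        leaders, f_leaders = state.leaders()
        f_best = float(state.fitness.min())
        f_worst = float(state.fitness.max())
        for i in range(config.pop_size):
            cands = gwo_candidates(state.positions[i], leaders, a, rng)
            if weighted:
                w = leader_weights(f_leaders, f_best, f_worst)
                x_new = sum(wk * ck for wk, ck in zip(w, cands))
            else:
                x_new = sum(cands) / 3.0
            x_new = reflect_bounds(x_new, space.lower, space.upper)
            state.positions[i] = x_new
            state.fitness[i] = state.evaluate(x_new)
        state.refresh_best()
        curve[t] = state.best_fitness
        div[t] = population_diversity(state.positions, space)
    return OptimizationResult(state.best_position, state.best_fitness, curve,
                              div, state.evaluations, config.seed, "gwo",
                              space.maximize)


def _run_hybrid(space: SearchSpace, config: OptimizerConfig) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    if config.chaotic_map == "none":
        positions = rng.uniform(space.lower, space.upper,
                                size=(config.pop_size, space.dim))
    else:
        positions = chaotic_init(config.pop_size, space, rng, config.chaotic_map)
    state = _State(space, positions)
    T = config.max_iter
    curve = np.empty(T)
    div = np.empty(T)
    frac_start, frac_end = config.whale_fraction_schedule
    for t in range(T):
        a = convergence_factor(t, T, config.convergence_mode)
        progress = t / max(T - 1, 1)
        frac = frac_start + (frac_end - frac_start) * progress
        n_whale = int(np.clip(round(frac * config.pop_size), 1,
                              config.pop_size - 1))
        whale_idx = np.arange(n_whale)
        wolf_idx = np.arange(n_whale, config.pop_size)
        wolf_leaders, wolf_f = state.leaders(wolf_idx)
        alpha = wolf_leaders[0]
        f_best = float(state.fitness.min())
        f_worst = float(state.fitness.max())

        for i in whale_idx:
            x = state.positions[i]
            r1, r2 = rng.random(2)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            p = rng.random()
            l = rng.uniform(-1.0, 1.0)
            if p < 0.5 and abs(A) < 1:
                # hierarchical leadership: weighted three-leader update
                leaders, f_leaders = state.leaders()
                cands = gwo_candidates(x, leaders, a, rng)
                w = leader_weights(f_leaders, f_best, f_worst)
                x_new = sum(wk * ck for wk, ck in zip(w, cands))
            elif p < 0.5:
                j = int(rng.integers(config.pop_size))
                x_new = random_search_update(state.positions[j], x, A, C)
            else:
                x_new = hybrid_spiral_update(x, state.best_position, alpha,
                                             C, config.b, l)
            x_new = reflect_bounds(x_new, space.lower, space.upper)
            f_new = state.evaluate(x_new)
            if f_new < state.fitness[i]:  # greedy (improve-only) acceptance
                state.positions[i] = x_new
                state.fitness[i] = f_new

        for i in wolf_idx:
            cands = gwo_candidates(state.positions[i], wolf_leaders, a, rng)
            w = leader_weights(wolf_f, f_best, f_worst)
            x_new = sum(wk * ck for wk, ck in zip(w, cands))
            x_new = reflect_bounds(x_new, space.lower, space.upper)
            f_new = state.evaluate(x_new)
            if f_new < state.fitness[i]:
                state.positions[i] = x_new
                state.fitness[i] = f_new

        if config.elite_exchange and len(wolf_idx) and len(whale_idx):
            bw = whale_idx[int(np.argmin(state.fitness[whale_idx]))]
            aw = wolf_idx[int(np.argmin(state.fitness[wolf_idx]))]
            worst_wolf = wolf_idx[int(np.argmax(state.fitness[wolf_idx]))]
            worst_whale = whale_idx[int(np.argmax(state.fitness[whale_idx]))]
            if worst_wolf != aw:
                state.positions[worst_wolf] = state.positions[bw].copy()
                state.fitness[worst_wolf] = state.fitness[bw]
            if worst_whale != bw:
                state.positions[worst_whale] = state.positions[aw].copy()
                state.fitness[worst_whale] = state.fitness[aw]

        if config.perturb_period and (t + 1) % config.perturb_period == 0 and t < T - 1:
            state.positions, victims = perturb(state.positions, state.fitness,
                                               space, rng,
                                               config.perturb_fraction)
            for v in victims:
                state.fitness[v] = state.evaluate(state.positions[v])

        state.refresh_best()
        curve[t] = state.best_fitness
        div[t] = population_diversity(state.positions, space)
    return OptimizationResult(state.best_position, state.best_fitness, curve,
                              div, state.evaluations, config.seed, "woa_gwo",
                              space.maximize)


def run_optimizer(space: SearchSpace, config: OptimizerConfig,
                  algorithm: str = "woa_gwo") -> OptimizationResult:
    """Run one of the three optimizers on a search space.

    ``algorithm`` is ``"woa"``, ``"gwo"`` or ``"woa_gwo"``.  The same seed
    always produces a bit-identical result.
    """
    if algorithm == "woa":
        return _run_woa(space, config)
    if algorithm == "gwo":
        return _run_gwo(space, config)
    if algorithm == "woa_gwo":
        return _run_hybrid(space, config)
    raise ValueError(f"unknown algorithm {algorithm!r}")
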