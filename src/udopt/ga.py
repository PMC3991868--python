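"""Real-coded genetic algorithm for box-constrained surface maximization.

Each candidate solution is one chromosome of real genes, one per factor.
Generations apply rank-based roulette selection with elitism, arithmetic
blend crossover and per-gene uniform-reset mutation, with offspring clipped
to the box; several independently seeded restarts guard against premature
convergence and the overall best is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

__all__ = ["GAConfig", "GAResult", "optimize", "maximize_titer", "HULL_BOX", "LEVEL_BOX"]

#: Factor box spanned by the uniform-design level grids (Asn, Glu, Pro; mg/L).
LEVEL_BOX = (np.array([50.0, 200.0, 50.0]), np.array([185.0, 380.0, 185.0]))
#: Box extended to the hull of the unseen test conditions.
HULL_BOX = (np.array([50.0, 200.0, 50.0]), np.array([200.0, 400.0, 200.0]))


@dataclass
class GAConfig:
    population_size: int = 20
    crossover_prob: float = 0.4
    mutation_prob: float = 0.2
    max_generations: int = 100
    n_restarts: int = 10
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass
class GAResult:
    best_x: np.ndarray
    best_fitness: float
    traces: list[list[float]]  # per-restart population-best fitness per generation
    winner_restart: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "best_x": self.best_x.tolist(),
                "best_fitness": self.best_fitness,
                "winner_restart": self.winner_restart,
                "traces": self.traces,
            }, fh, indent=2)


def _evaluate(fitness: Callable[[np.ndarray], np.ndarray], pop: np.ndarray) -> np.ndarray:
    vals = np.asarray(fitness(pop), dtype=float).ravel()
    if not np.all(np.isfinite(vals)):
        bad = pop[int(np.argmax(~np.isfinite(vals)))]
        raise ValueError(f"non-finite fitness at point {bad.tolist()}")
    return vals


def _run_once(fitness, lo, hi, config: GAConfig, rng: np.random.Generator):
    n_genes = len(lo)
    pop = rng.uniform(lo, hi, size=(config.population_size, n_genes))
    vals = _evaluate(fitness, pop)
    best_idx = int(np.argmax(vals))
    best_x, best_val = pop[best_idx].copy(), float(vals[best_idx])
    trace = [best_val]
    for _ in range(config.max_generations):
        # rank-based roulette: worst gets weight 1, best gets weight N
        order = np.argsort(vals)
        ranks = np.empty(config.population_size)
        ranks[order] = np.arange(1, config.population_size + 1)
        probs = ranks / ranks.sum()
        n_elite = config.elitism
        elite = pop[np.argsort(vals)[::-1][:n_elite]].copy()
        parents = pop[rng.choice(config.population_size, size=2 * (config.population_size - n_elite),
                                 p=probs)]
        p1, p2 = parents[0::2], parents[1::2]
        alpha = rng.uniform(0.0, 1.0, size=p1.shape)
        do_cross = rng.random(len(p1)) < config.crossover_prob
        children = np.where(do_cross[:, None], alpha * p1 + (1.0 - alpha) * p2, p1)
        mutate = rng.random(children.shape) < config.mutation_prob
        children = np.where(mutate, rng.uniform(lo, hi, size=children.shape), children)
        pop = np.clip(np.vstack([elite, children]), lo, hi)
        vals = _evaluate(fitness, pop)
        gen_best = int(np.argmax(vals))
        if vals[gen_best] > best_val:
            best_val = float(vals[gen_best])
            best_x = pop[gen_best].copy()
        trace.append(float(vals[gen_best]))  # population best; monotone when elitism >= 1
    return best_x, best_val, trace


def optimize(fitness: Callable[[np.ndarray], np.ndarray],
             box: tuple[np.ndarray, np.ndarray],
             config: GAConfig | None = None) -> GAResult:
    """Maximize a surface evaluator over a box with seeded GA restarts.

    ``fitness`` must accept an (n, s) array of candidate points and return n
    values; both fitted surrogates in this package satisfy that contract.
    """
    config = config or GAConfig()
    lo, hi = (np.asarray(v, dtype=float) for v in box)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo <= hi)):
        raise ValueError("box bounds must be finite with lower <= upper")
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.n_restarts)
    traces, bests = [], []
    for s in seeds:
        bx, bv, trace = _run_once(fitness, lo, hi, config, np.random.default_rng(int(s)))
        bests.append((bv, bx))
        traces.append(trace)
    winner = int(np.argmax([b[0] for b in bests]))
    return GAResult(best_x=bests[winner][1], best_fitness=bests[winner][0],
                    traces=traces, winner_restart=winner)


def maximize_titer(surrogate: Callable[[np.ndarray], np.ndarray],
                   config: GAConfig | None = None,
                   box: Literal["levels", "hull"] | tuple = "hull") -> GAResult:
    """Convenience wrapper: maximize a fitted surrogate over the factor box.

    ``box="levels"`` uses the design level ranges; ``box="hull"`` extends them
    to cover the unseen test conditions (Asn/Pro up to 200, Glu up to 400).
    """
    if box == "levels":
        bounds = LEVEL_BOX
    elif box == "hull":
        bounds = HULL_BOX
    else:
        bounds = box
    return optimize(surrogate, bounds, config)
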