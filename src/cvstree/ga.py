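"""Genetic-algorithm wrapper feature selection for regression trees.

Each chromosome is a length-p bit string over the predictors (1 = the
variable may enter the tree).  Fitness is the held-out performance of the
model the chromosome encodes: a regression tree is fitted on the training
split restricted to the masked columns and scored by RMSE on the
validation split, so lower fitness is better and the search optimises
generalisation rather than training fit.

The generational loop uses truncation selection (parents drawn from the
better half of the population), single-point crossover applied with
probability ``crossover_prob`` (otherwise the parents are cloned),
independent per-bit mutation, and elitism (the best few members copied
unchanged, which makes the best-so-far fitness trace non-increasing).
Evolution stops when the best fitness has not improved by more than a
relative ``stall_tolerance`` (default 0.01%) within ``stall_generations``
(default 100) consecutive generations, or at the ``max_generations``
safeguard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tree import CohortTable, GrowthConfig, fit_tree, predict, rmse

FeatureMask = np.ndarray  # length-p uint8 vector with at least one bit set


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_fraction: float = 0.05
    stall_generations: int = 100
    stall_tolerance: float = 1e-4
    max_generations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0.0 < self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in (0, 1]")
        if not 0.0 < self.mutation_prob < 1.0:
            raise ValueError("mutation_prob must be in (0, 1)")
        if not 0.0 <= self.elitism_fraction < 1.0:
            raise ValueError("elitism_fraction must be in [0, 1)")
        if self.stall_generations < 1 or self.max_generations < 1:
            raise ValueError("generation counts must be >= 1")
        if self.stall_tolerance < 0:
            raise ValueError("stall_tolerance must be non-negative")


@dataclass
class GaResult:
    best_mask: FeatureMask
    best_fitness: float
    generations_run: int
    fitness_trace: list[float] = field(default_factory=list)


def _repair(mask: FeatureMask, rng: np.random.Generator, donor: FeatureMask | None = None) -> FeatureMask:
    """Guarantee at least one set bit; degenerate all-zero masks are illegal.

    When a donor is given (crossover), one of the donor's set bits is
    copied; otherwise a uniformly random bit is set.
    """
    if mask.any():
        return mask
    if donor is not None and donor.any():
        j = rng.choice(np.flatnonzero(donor))
    else:
        j = rng.integers(mask.size)
    mask[j] = 1
    return mask


def init_population(p: int, config: GaConfig, rng: np.random.Generator) -> list[FeatureMask]:
    """Random initial population covering the whole solution space.

    Each bit is a fair coin, so every variable has selection probability
    1/2 in every member; all-zero draws are repaired.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    pop = []
    for _ in range(config.population_size):
        mask = (rng.random(p) < 0.5).astype(np.uint8)
        pop.append(_repair(mask, rng))
    return pop


def crossover(a: FeatureMask, b: FeatureMask, rng: np.random.Generator) -> tuple[FeatureMask, FeatureMask]:
    """Single-point crossover of two equal-length parents.

    The cut is uniform on [1, p-1]; each offspring takes one parent's bits
    before the cut and the other's after.  Offspring bits therefore always
    come from a parent (no new alleles).  For p = 1 the parents are cloned.
    """
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    p = a.size
    if p < 2:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, p))
    c1 = np.concatenate([a[:cut], b[cut:]]).astype(np.uint8)
    c2 = np.concatenate([b[:cut], a[cut:]]).astype(np.uint8)
    return _repair(c1, rng, donor=a), _repair(c2, rng, donor=b)


def mutate(mask: FeatureMask, mutation_prob: float, rng: np.random.Generator) -> FeatureMask:
    """Flip each bit independently with probability ``mutation_prob``."""
    flips = rng.random(mask.size) < mutation_prob
    out = np.where(flips, 1 - mask, mask).astype(np.uint8)
    return _repair(out, rng)


def fitness(
    mask: FeatureMask,
    train: CohortTable,
    validation: CohortTable,
    growth: GrowthConfig | None = None,
) -> float:
    """Validation RMSE of the tree fitted on the masked training columns."""
    from ._fast_tree import fit_predict

    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("feature mask must select at least one column")
    if train.columns != validation.columns:
        raise ValueError("train and validation tables must share columns")
    growth = growth or GrowthConfig()
    cols = np.flatnonzero(mask)
    y_pred = fit_predict(
        train.X[:, cols], train.y, validation.X[:, cols],
        growth.min_node_size, growth.max_depth,
    )
    return rmse(validation.y, y_pred)


def evolve(
    train: CohortTable,
    validation: CohortTable,
    config: GaConfig | None = None,
    growth: GrowthConfig | None = None,
) -> GaResult:
    """Run the generational loop and return the best-ever mask and fitness.

    ``fitness_trace`` holds the best-so-far fitness after each generation,
    which elitism makes non-increasing.  Identical seed, config and data
    reproduce the result exactly.
    """
    config = config or GaConfig()
    growth = growth or GrowthConfig()
    rng = np.random.default_rng(config.seed)
    p = train.p
    pop = init_population(p, config, rng)

    cache: dict[bytes, float] = {}

    def evaluate(mask: FeatureMask) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = fitness(mask, train, validation, growth)
        return cache[key]

    n_elite = math.ceil(config.elitism_fraction * config.population_size)
    best_mask: FeatureMask | None = None
    best_fit = np.inf
    stall_anchor = np.inf  # best fitness at the last counted improvement
    last_improvement = 0
    trace: list[float] = []
    gen = 0

    for gen in range(config.max_generations):
        fits = np.array([evaluate(m) for m in pop])
        order = np.argsort(fits, kind="stable")
        gen_best = float(fits[order[0]])
        if gen_best < best_fit:
            best_fit = gen_best
            best_mask = pop[order[0]].copy()
        trace.append(best_fit)

        # stall rule: only a relative improvement > stall_tolerance resets
        # the window
        if not np.isfinite(stall_anchor):
            stall_anchor = gen_best
            last_improvement = gen
        elif stall_anchor > 0 and (stall_anchor - gen_best) / stall_anchor > config.stall_tolerance:
            stall_anchor = gen_best
            last_improvement = gen
        if gen - last_improvement >= config.stall_generations:
            break
        if gen == config.max_generations - 1:
            break

        elites = [pop[i].copy() for i in order[:n_elite]]
        parent_pool = order[: max(2, config.population_size // 2)]
        children: list[FeatureMask] = []
        while len(children) < config.population_size - n_elite:
            i, j = rng.choice(parent_pool, size=2, replace=False)
            if rng.random() < config.crossover_prob:
                c1, c2 = crossover(pop[i], pop[j], rng)
            else:
                c1, c2 = pop[i].copy(), pop[j].copy()
            children.append(mutate(c1, config.mutation_prob, rng))
            if len(children) < config.population_size - n_elite:
                children.append(mutate(c2, config.mutation_prob, rng))
        pop = elites + children

    assert best_mask is not None
    return GaResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        generations_run=gen + 1,
        fitness_trace=trace,
    )
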