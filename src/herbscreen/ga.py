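"""Genetic algorithm over herb bitstrings, guided by a surrogate scorer.

Each individual is a binary vector over the herb vocabulary; a set bit
means the herb is part of the candidate combination.  The fitness to be
*minimized* is

    fitness(X) = P(ineffective | X) + (|X| - N)^2

where ``P(ineffective | X) = 1 - scorer(X)`` comes from the trained
classifier and N is the target number of herbs in the combination.  The
squared size penalty dominates early evolution (a random half-density
individual over 334 herbs starts with a penalty in the tens of thousands),
so runs show two phases: the population first collapses to combinations of
exactly N herbs, then optimizes which N herbs to keep.

Selection is roulette-wheel on inverse fitness, crossover is uniform
per-position swapping, and the global best individual is carried into every
generation unchanged (elitism of one), which makes the best-fitness trace
non-increasing.  Mutation applies one subset move to every offspring: add a
random absent herb, drop a random present herb, or swap one for another
(one-point and rate-gated modes are available as alternatives).

The mutation default matters twice over.  First, with a 334-bit genome, 10
individuals and 1000 generations, gating mutation at a 0.1 per-offspring
probability supplies under one flip per generation, which cannot carry the
population from random half-density initialization (~167 set bits) down to
the size constraint within the iteration budget, no matter how selection is
transformed; mutating every offspring restores the two-phase trajectory in
which the size penalty reaches zero well before the iteration cap.  Second,
once individuals sit at the target size, any single bit flip crosses a
size-penalized intermediate that elitism rejects; the size-preserving swap
move keeps the equal-size shell connected so the surrogate probability can
still be optimized in the late phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from herbscreen.prescriptions import HerbVocabulary

__all__ = [
    "GAConfig",
    "Individual",
    "FitnessTrace",
    "fitness",
    "evaluate_population",
    "initialize_population",
    "roulette_select",
    "crossover",
    "mutate",
    "evolve",
    "decode_combination",
    "export_trace_csv",
    "export_result_json",
]

#: Floor added to fitness before inverting it into a selection weight.
SELECTION_EPS = 1e-6

Scorer = Callable[[np.ndarray], "np.ndarray | float"]


@dataclass(frozen=True)
class GAConfig:
    """Evolution parameters; defaults follow the published search settings."""

    population_size: int = 10
    max_iterations: int = 1000
    n_parents: int = 5
    crossover_rate: float = 0.1
    mutation_rate: float = 0.1
    target_size: int = 12
    seed: int = 0
    init_density: float = 0.5
    selection: str = "inverse"  # or "rank"
    crossover_mode: str = "uniform"  # or "single_point"
    mutation_mode: str = "subset"  # or "one_point", "per_individual", "per_bit"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_parents < 1 or self.n_parents > self.population_size:
            raise ValueError("need 1 <= n_parents <= population_size")
        for name in ("crossover_rate", "mutation_rate", "init_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.selection not in ("inverse", "rank"):
            raise ValueError("selection must be 'inverse' or 'rank'")
        if self.crossover_mode not in ("uniform", "single_point"):
            raise ValueError("crossover_mode must be 'uniform' or 'single_point'")
        if self.mutation_mode not in ("subset", "one_point", "per_individual", "per_bit"):
            raise ValueError(
                "mutation_mode must be 'subset', 'one_point', 'per_individual' or 'per_bit'"
            )


@dataclass(frozen=True)
class Individual:
    """A candidate herb combination and its (lower-is-better) fitness."""

    genes: np.ndarray  # (vocab_size,) uint8 in {0,1}
    fitness: float

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=np.uint8)
        if genes.ndim != 1 or (genes.size and genes.max() > 1):
            raise ValueError("genes must be a 1-D 0/1 vector")
        if self.fitness < 0:
            raise ValueError("fitness must be non-negative")
        object.__setattr__(self, "genes", genes)

    @property
    def size(self) -> int:
        return int(self.genes.sum())


@dataclass(frozen=True)
class FitnessTrace:
    """Per-iteration record of an evolution run."""

    best_fitness: np.ndarray  # (iterations,) global best after each iteration
    population_fitness: np.ndarray  # (iterations, population_size)
    best_size: np.ndarray  # (iterations,) herb count of the global best
    best_snapshots: tuple[tuple[int, Individual], ...]  # (iteration, new global best)

    def __len__(self) -> int:
        return len(self.best_fitness)


def _score(scorer: Scorer, genes: np.ndarray) -> np.ndarray:
    """Apply a scorer to a matrix of gene rows, validating the output range."""
    out = np.atleast_1d(np.asarray(scorer(genes), dtype=np.float64))
    if out.shape != (genes.shape[0],):
        raise ValueError("scorer must return one probability per gene row")
    if np.any((out < 0.0) | (out > 1.0)) or not np.all(np.isfinite(out)):
        raise ValueError("scorer returned values outside [0, 1]")
    return out


def fitness(genes: np.ndarray, scorer: Scorer, target_size: int) -> float:
    """Predicted ineffectiveness plus squared deviation from the target size."""
    genes = np.asarray(genes, dtype=np.uint8)
    p_eff = float(_score(scorer, genes[None, :])[0])
    return (1.0 - p_eff) + float((int(genes.sum()) - target_size) ** 2)


def evaluate_population(genes: np.ndarray, scorer: Scorer, target_size: int) -> np.ndarray:
    """Vectorized fitness of a (pop, vocab) gene matrix."""
    p_eff = _score(scorer, genes)
    sizes = genes.sum(axis=1).astype(np.int64)
    return (1.0 - p_eff) + (sizes - target_size) ** 2


def initialize_population(
    config: GAConfig, vocab_size: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Seeded Bernoulli(init_density) gene matrix of shape (pop, vocab)."""
    if vocab_size < config.target_size:
        raise ValueError(
            f"vocabulary size {vocab_size} is smaller than target size {config.target_size}"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return (
        rng.random((config.population_size, vocab_size)) < config.init_density
    ).astype(np.uint8)


def _selection_weights(fitnesses: np.ndarray, mode: str) -> np.ndarray:
    if mode == "rank":
        # worst rank weight 1, best rank weight pop_size
        order = np.argsort(np.argsort(fitnesses))
        w = (len(fitnesses) - order).astype(np.float64)
    else:
        w = 1.0 / (fitnesses + SELECTION_EPS)
    return w / w.sum()


def roulette_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    n_parents: int,
    rng: np.random.Generator,
    mode: str = "inverse",
) -> np.ndarray:
    """Sample parents with replacement, weight 1/(fitness + eps).

    Fitness is minimized, so classical roulette proportionality is applied
    to the inverse fitness (rank weighting available as ``mode='rank'``).
    """
    population = np.asarray(population)
    if population.shape[0] == 0:
        raise ValueError("population is empty")
    probs = _selection_weights(np.asarray(fitnesses, dtype=np.float64), mode)
    idx = rng.choice(population.shape[0], size=n_parents, replace=True, p=probs)
    return population[idx]


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mode: str = "uniform",
) -> tuple[np.ndarray, np.ndarray]:
    """Swap genes between two parents; returns two children.

    Uniform mode swaps each position independently with probability
    ``rate``; single-point mode performs a classical one-point crossover
    with probability ``rate`` per pair.
    """
    parent_a = np.asarray(parent_a, dtype=np.uint8)
    parent_b = np.asarray(parent_b, dtype=np.uint8)
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must have equal gene lengths")
    child_a, child_b = parent_a.copy(), parent_b.copy()
    if mode == "uniform":
        swap = rng.random(parent_a.shape[0]) < rate
        child_a[swap], child_b[swap] = parent_b[swap], parent_a[swap]
    else:
        if rng.random() < rate and parent_a.shape[0] > 1:
            point = int(rng.integers(1, parent_a.shape[0]))
            child_a[point:], child_b[point:] = parent_b[point:], parent_a[point:]
    return child_a, child_b


def mutate(
    genes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mode: str = "per_individual",
) -> np.ndarray:
    """Flip bits (0 <-> 1) in a copy of ``genes``.

    Per-individual mode (default of this operator): with probability
    ``rate``, one uniformly chosen bit is flipped, otherwise the individual
    is unchanged.  Subset mode applies exactly one move chosen uniformly
    among {turn a random 0 into 1, turn a random 1 into 0, do both (a
    size-preserving swap)}; one-point mode flips one uniformly chosen bit;
    in both of those every call mutates and ``rate`` is ignored.  Per-bit
    mode flips every position independently with probability ``rate``.

    The swap move is what keeps the search space connected once the size
    penalty pins individuals to the target herb count: pure single-bit
    flips must pass through a size-penalized intermediate, which elitist
    selection rejects, freezing refinement of *which* herbs are kept.
    """
    genes = np.asarray(genes, dtype=np.uint8).copy()
    if mode == "subset":
        ones = np.flatnonzero(genes == 1)
        zeros = np.flatnonzero(genes == 0)
        move = int(rng.integers(3))  # 0 add, 1 remove, 2 swap
        add = move in (0, 2)
        remove = move in (1, 2)
        if remove and ones.size == 0:
            remove, add = False, True
        if add and zeros.size == 0:
            add = False
        if add:
            genes[zeros[int(rng.integers(zeros.size))]] = 1
        if remove:
            genes[ones[int(rng.integers(ones.size))]] = 0
    elif mode == "one_point":
        genes[int(rng.integers(genes.shape[0]))] ^= 1
    elif mode == "per_individual":
        if rng.random() < rate:
            pos = int(rng.integers(genes.shape[0]))
            genes[pos] ^= 1
    else:
        flips = rng.random(genes.shape[0]) < rate
        genes[flips] ^= 1
    return genes


def evolve(
    scorer: Scorer,
    config: GAConfig,
    vocab: HerbVocabulary | int,
    log: Callable[[str], None] | None = None,
) -> tuple[Individual, FitnessTrace]:
    """Run the full evolutionary search; returns the global best and its trace.

    Each iteration: record the trace, roulette-select ``n_parents`` parents,
    pair them randomly with replacement, produce offspring by crossover +
    mutation until ``population_size - 1`` children exist, and form the next
    population as the unchanged global best (elitism of one) plus the
    children.  The global best is therefore monotonically non-increasing in
    fitness across iterations.
    """
    vocab_size = vocab if isinstance(vocab, int) else vocab.size
    rng = np.random.default_rng(config.seed)

    pop = initialize_population(config, vocab_size, rng)
    fits = evaluate_population(pop, scorer, config.target_size)

    best_i = int(fits.argmin())
    best = Individual(pop[best_i].copy(), float(fits[best_i]))

    iters = config.max_iterations
    best_fitness = np.zeros(iters)
    best_size = np.zeros(iters, dtype=np.int64)
    pop_fitness = np.zeros((iters, config.population_size))
    snapshots: list[tuple[int, Individual]] = [(0, best)]

    for it in range(iters):
        parents = roulette_select(pop, fits, config.n_parents, rng, config.selection)
        children: list[np.ndarray] = []
        while len(children) < config.population_size - 1:
            pa, pb = parents[rng.integers(config.n_parents, size=2)]
            for child in crossover(pa, pb, config.crossover_rate, rng, config.crossover_mode):
                if len(children) < config.population_size - 1:
                    children.append(mutate(child, config.mutation_rate, rng, config.mutation_mode))
        pop = np.vstack([best.genes[None, :], np.array(children, dtype=np.uint8)])
        child_fits = evaluate_population(pop[1:], scorer, config.target_size)
        fits = np.concatenate([[best.fitness], child_fits])

        cand = int(fits.argmin())
        if fits[cand] < best.fitness:
            best = Individual(pop[cand].copy(), float(fits[cand]))
            snapshots.append((it + 1, best))
        best_fitness[it] = best.fitness
        best_size[it] = best.size
        pop_fitness[it] = fits
        if log is not None and (it + 1) % 100 == 0:
            log(
                f"iteration {it + 1:5d}/{iters}: best fitness {best.fitness:.6f} "
                f"(size {best.size}), population mean {fits.mean():.3f}"
            )

    trace = FitnessTrace(best_fitness, pop_fitness, best_size, tuple(snapshots))
    return best, trace


def decode_combination(
    best: Individual, vocab: HerbVocabulary, scorer: Scorer | None = None
) -> tuple[list[str], float | None]:
    """Herb names of the set bits (vocabulary order) and their scored probability."""
    names = [vocab.names[i] for i in np.flatnonzero(best.genes)]
    prob = None
    if scorer is not None:
        prob = float(_score(scorer, np.asarray(best.genes, dtype=np.uint8)[None, :])[0])
    return names, prob


def export_trace_csv(trace: FitnessTrace, path: str | Path) -> None:
    """CSV with columns iteration, best_fitness, mean_fitness, best_size."""
    pd.DataFrame(
        {
            "iteration": np.arange(1, len(trace) + 1),
            "best_fitness": trace.best_fitness,
            "mean_fitness": trace.population_fitness.mean(axis=1),
            "best_size": trace.best_size,
        }
    ).to_csv(path, index=False, lineterminator="\n")


def export_result_json(
    best: Individual,
    vocab: HerbVocabulary,
    config: GAConfig,
    path: str | Path,
    effective_prob: float | None = None,
    extra: dict | None = None,
) -> None:
    """Structured result: herb names, gene indices, probability, fitness, config."""
    payload = {
        "herbs": [vocab.names[i] for i in np.flatnonzero(best.genes)],
        "gene_indices": [int(i) for i in np.flatnonzero(best.genes)],
        "n_herbs": best.size,
        "fitness": best.fitness,
        "effective_probability": effective_prob,
        "config": asdict(config),
        "seed": config.seed,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
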