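"""Genetic-algorithm optimization of the 11 feature weights.

Fitness is the mean out-of-bag accuracy of precomputed-kernel SVMs over
bootstrap resamples of the training set (bagging).  The GA is the
simplest canonical one consistent with the stated operator rates:
fitness-proportional selection, single-point crossover, per-gene uniform
mutation steps bounded by the configured step size, and one elite.
Identically scoring finalists are separated by full cross-validation on
the original training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .descriptor import MoleculeDescriptor
from .kernel_svm import SvmGridConfig, train_select
from .pairdist import WeightVector, pairwise_matrix

logger = logging.getLogger(__name__)

N_GENES = 11


@dataclass
class GaConfig:
    """GA hyper-parameters; defaults follow the full-scale settings."""

    population_size: int = 32
    mutation_prob: float = 0.15
    crossover_prob: float = 0.8
    generations: int = 20
    step_bound: float = 0.1
    n_bags: int = 1000
    seed: int = 0
    svm_config: SvmGridConfig = field(default_factory=SvmGridConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_prob <= 1.0 and 0.0 <= self.crossover_prob <= 1.0):
            raise ValueError("operator probabilities must lie in [0, 1]")
        if self.step_bound < 0:
            raise ValueError("step bound must be non-negative")
        if min(self.population_size, self.generations, self.n_bags) < 1:
            raise ValueError("population, generations and bag count must be >= 1")


@dataclass
class Genome:
    weights: WeightVector
    fitness: Optional[float] = None

    def genes(self) -> np.ndarray:
        return self.weights.as_array()


def init_population(initial: WeightVector, cfg: GaConfig, rng: np.random.Generator) -> list[Genome]:
    """Seed population: the unperturbed initial vector plus uniform jitter."""
    population = [Genome(initial)]
    base = initial.as_array()
    for _ in range(cfg.population_size - 1):
        step = rng.uniform(-cfg.step_bound, cfg.step_bound, size=N_GENES)
        genes = np.clip(base + step, 0.0, None)
        population.append(Genome(WeightVector.from_array(genes)))
    return population


def _draw_bag(
    n: int, labels: np.ndarray, rng: np.random.Generator, max_retries: int = 10
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Bootstrap in-bag / out-of-bag index split with both classes in-bag."""
    for _ in range(max_retries):
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size == 0:
            continue
        if len(np.unique(labels[in_bag])) < 2:
            continue
        return in_bag, oob
    return None


def bagged_fitness(
    genome: Genome,
    descriptors: Sequence[MoleculeDescriptor],
    labels: Sequence[int],
    cfg: GaConfig,
    rng: np.random.Generator,
) -> float:
    """Mean out-of-bag accuracy over ``cfg.n_bags`` bootstrap resamples.

    The full pairwise distance matrix is computed once per genome and
    sub-indexed per bag, so the expensive matching runs once.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    D = pairwise_matrix(descriptors, genome.weights)
    n = len(descriptors)
    accuracies = []
    for bag in range(cfg.n_bags):
        drawn = _draw_bag(n, y, rng)
        if drawn is None:
            logger.warning("bag %d skipped: could not draw a two-class bag", bag)
            continue
        in_bag, oob = drawn
        model = train_select(D.submatrix(in_bag), y[in_bag], cfg.svm_config)
        scores = model.decision_scores(D.values[np.ix_(oob, in_bag)])
        pred = (scores > 0).astype(int)
        accuracies.append(float(np.mean(pred == y[oob])))
    if not accuracies:
        raise RuntimeError("no usable bags drawn")
    return float(np.mean(accuracies))


def evolve(population: Sequence[Genome], cfg: GaConfig, rng: np.random.Generator) -> list[Genome]:
    """One GA generation: selection, crossover, mutation, 1-elitism.

    Offspring gene values are clipped at 0; the best genome of the current
    generation survives unchanged, so best fitness never decreases.
    """
    if any(g.fitness is None for g in population):
        raise ValueError("all fitnesses must be evaluated before evolve()")
    pop = list(population)
    fitnesses = np.array([g.fitness for g in pop])
    elite = pop[int(np.argmax(fitnesses))]

    total = fitnesses.sum()
    if total > 0:
        probs = fitnesses / total
    else:
        probs = np.full(len(pop), 1.0 / len(pop))
    selected = [pop[i] for i in rng.choice(len(pop), size=len(pop), p=probs)]

    children: list[Genome] = []
    for k in range(0, len(selected), 2):
        pair = selected[k : k + 2]
        genes = [g.genes().copy() for g in pair]
        if len(genes) == 2 and rng.random() < cfg.crossover_prob:
            point = int(rng.integers(1, N_GENES))
            genes[0][point:], genes[1][point:] = (
                genes[1][point:].copy(),
                genes[0][point:].copy(),
            )
        for gene_vec in genes:
            mask = rng.random(N_GENES) < cfg.mutation_prob
            steps = rng.uniform(-cfg.step_bound, cfg.step_bound, size=N_GENES)
            gene_vec[mask] += steps[mask]
            np.clip(gene_vec, 0.0, None, out=gene_vec)
            children.append(Genome(WeightVector.from_array(gene_vec)))
    children = children[: len(pop)]
    children[0] = replace(elite)
    return children


def select_among_ties(
    tied: Sequence[Genome],
    descriptors: Sequence[MoleculeDescriptor],
    labels: Sequence[int],
    svm_config: Optional[SvmGridConfig] = None,
) -> Genome:
    """Break fitness ties by full CV accuracy on the original training set.

    Remaining ties resolve to the canonically smallest weight vector.
    """
    if not tied:
        raise ValueError("need at least one tied genome")
    if len(tied) == 1:
        return tied[0]
    y = np.asarray(labels, dtype=int)
    ranked = []
    for genome in tied:
        D = pairwise_matrix(descriptors, genome.weights)
        model = train_select(D, y, svm_config)
        ranked.append((-model.cv_accuracy, tuple(genome.genes()), genome))
    ranked.sort(key=lambda item: item[:2])
    return ranked[0][2]


@dataclass
class OptimizationResult:
    best: Genome
    history: list[dict]


def optimize_weights(
    descriptors: Sequence[MoleculeDescriptor],
    labels: Sequence[int],
    cfg: GaConfig,
    initial: Optional[WeightVector] = None,
) -> OptimizationResult:
    """Run the full GA loop and return the tie-broken best genome.

    The whole trajectory is driven by one seeded generator, so a fixed
    ``cfg.seed`` makes the optimization bit-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    initial = initial or WeightVector()
    population = init_population(initial, cfg, rng)

    history: list[dict] = []
    for generation in range(cfg.generations + 1):
        for genome in population:
            if genome.fitness is None:
                genome.fitness = bagged_fitness(genome, descriptors, labels, cfg, rng)
        fitnesses = [g.fitness for g in population]
        history.append(
            {
                "generation": generation,
                "best_fitness": max(fitnesses),
                "mean_fitness": float(np.mean(fitnesses)),
            }
        )
        logger.info(
            "generation %d: best %.4f mean %.4f",
            generation,
            history[-1]["best_fitness"],
            history[-1]["mean_fitness"],
        )
        if generation < cfg.generations:
            population = evolve(population, cfg, rng)

    best_fitness = max(g.fitness for g in population)
    tied = [g for g in population if g.fitness == best_fitness]
    best = select_among_ties(tied, descriptors, labels, cfg.svm_config)
    return OptimizationResult(best=best, history=history)
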