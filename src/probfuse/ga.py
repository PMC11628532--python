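"""Genetic algorithm over simplex-constrained ensemble fusion weights.

A chromosome is a K-vector of non-negative weights summing to 1 (for two
models, the classic (alpha, beta) pair with alpha + beta = 1).  Fitness of
a chromosome is the overall accuracy of the argmax predictions of the
weighted-average ensemble it defines on the supplied bundle.  The loop is
generational with elitism, tournament or roulette-wheel parent selection,
coordinate-exchange crossover with simplex repair, and a single-coordinate
perturbation mutation that rescales the remaining coordinates so the sum
stays 1.

The initial population contains the K single-model vertex chromosomes and
the equal-weight chromosome ahead of uniform random simplex draws, so the
search space always includes every standalone model and the simple
average as baselines; with elitism the optimizer therefore never returns
a fitness below the best of those.  An exhaustive simplex grid search
(:func:`grid_search_oracle`) serves as an independent check for small K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .fusion import SIMPLEX_TOL, WeightVector
from .io import ModelBundle

#: raw offspring whose coordinate sum is below this are reset to uniform.
_DEGENERATE_SUM = 1e-12


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults are deliberately small-scale, conventional choices: a
    population of 30 evolved for up to 50 generations with tournament
    selection (size 3), 0.9 crossover rate, 0.2 per-chromosome mutation
    rate with perturbations uniform on +/- ``mutation_scale``, and one
    elite carried over unchanged (which makes the best-fitness trace
    monotone).  ``fitness_target`` optionally stops the run early once the
    best fitness reaches it.
    """

    population_size: int = 30
    max_generations: int = 50
    selection: str = "tournament"
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_scale: float = 0.05
    elitism: int = 1
    fitness_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValidationError("max_generations must be >= 1")
        if self.selection not in ("tournament", "roulette"):
            raise ValidationError(f"unknown selection scheme {self.selection!r}")
        if self.tournament_size < 1:
            raise ValidationError("tournament_size must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.mutation_scale <= 0:
            raise ValidationError("mutation_scale must be positive")
        if not 0 <= self.elitism < self.population_size:
            raise ValidationError("need 0 <= elitism < population_size")


@dataclass
class Chromosome:
    """One candidate weight vector, with its fitness once evaluated."""

    weights: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        self.weights = w
        if w.ndim != 1 or w.size < 2:
            raise ValidationError("chromosome needs >= 2 weights")
        if w.min() < -SIMPLEX_TOL or abs(w.sum() - 1.0) > SIMPLEX_TOL:
            raise ValidationError(f"chromosome off the simplex: {w}")


@dataclass(frozen=True)
class OptimizationResult:
    best_weights: WeightVector
    best_fitness: float
    fitness_trace: tuple[float, ...]
    mean_trace: tuple[float, ...]
    generations_run: int
    termination: str
    seed: int


def _ensemble_accuracy(w: np.ndarray, stacked: np.ndarray, labels: np.ndarray) -> float:
    fused = np.tensordot(w, stacked, axes=(0, 0))
    return float(np.mean(np.argmax(fused, axis=1) == labels))


def fitness(weights, bundle: ModelBundle) -> float:
    """Overall accuracy of the weighted-average ensemble's argmax predictions."""
    if bundle.labels is None:
        raise ValidationError("fitness needs a bundle with ground-truth labels")
    if isinstance(weights, WeightVector):
        if weights.model_names != bundle.model_names:
            raise ValidationError("weight names do not match bundle models")
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
        Chromosome(w)  # simplex validation
    if w.size != bundle.n_models:
        raise ValidationError(f"{w.size} weights for {bundle.n_models} models")
    return _ensemble_accuracy(w, bundle.stacked(), bundle.labels.labels)


def init_population(K: int, config: GAConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Seeded initial population on the K-simplex.

    The first min(K+1, population_size) chromosomes are deterministic
    baselines — the K vertices (each single model alone) followed by the
    equal-weight point — and the remainder are uniform simplex draws
    (symmetric Dirichlet(1)).
    """
    if K < 2:
        raise ValidationError(f"need >= 2 models, got K={K}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    baselines = [np.eye(K)[k] for k in range(K)] + [np.full(K, 1.0 / K)]
    population = [Chromosome(b) for b in baselines[: config.population_size]]
    n_random = config.population_size - len(population)
    if n_random > 0:
        draws = rng.dirichlet(np.ones(K), size=n_random)
        population += [Chromosome(d) for d in draws]
    return population


def select(population: list[Chromosome], config: GAConfig, rng: np.random.Generator) -> Chromosome:
    """Choose one parent; all fitnesses must already be evaluated.

    Tournament: the fittest of ``tournament_size`` chromosomes drawn
    without replacement (ties go to the earlier-positioned chromosome).
    Roulette: draw with probability proportional to fitness, falling back
    to a uniform draw when every fitness is 0.
    """
    if not population:
        raise ValidationError("cannot select from an empty population")
    fits = [c.fitness for c in population]
    if any(f is None for f in fits):
        raise ValidationError("select requires all fitnesses evaluated")
    if config.selection == "tournament":
        size = min(config.tournament_size, len(population))
        idx = np.sort(rng.choice(len(population), size=size, replace=False))
        best = idx[0]
        for i in idx[1:]:
            if population[i].fitness > population[best].fitness:
                best = i
        return population[best]
    total = float(np.sum(fits))
    if total <= 0.0:
        i = int(rng.integers(len(population)))
    else:
        i = int(rng.choice(len(population), p=np.asarray(fits) / total))
    return population[i]


def crossover(
    p1: Chromosome, p2: Chromosome, rng: np.random.Generator | None = None
) -> tuple[Chromosome, Chromosome]:
    """Coordinate-exchange crossover with simplex repair.

    Offspring exchange complementary coordinate blocks between the
    parents; for K=2 this is the deterministic pairing
    ``(a1, b2)`` / ``(a2, b1)``, for K>2 the block is a random proper
    subset of coordinates (requires ``rng``).  Raw offspring generally
    leave the simplex, so each is divided by its coordinate sum; a raw sum
    of 0 resets that offspring to uniform weights.
    """
    k = p1.weights.size
    if p2.weights.size != k:
        raise ValidationError("parents must have the same number of weights")
    if k == 2:
        mask = np.array([True, False])
    else:
        if rng is None:
            raise ValidationError("crossover with K > 2 requires an rng")
        mask = rng.random(k) < 0.5
        if mask.all() or not mask.any():  # keep the exchange non-trivial
            mask[int(rng.integers(k))] ^= True
    raw1 = np.where(mask, p1.weights, p2.weights)
    raw2 = np.where(mask, p2.weights, p1.weights)

    def repair(raw: np.ndarray) -> Chromosome:
        s = raw.sum()
        if s <= _DEGENERATE_SUM:
            return Chromosome(np.full(k, 1.0 / k))
        return Chromosome(raw / s)

    return repair(raw1), repair(raw2)


def mutate(c: Chromosome, config: GAConfig, rng: np.random.Generator) -> Chromosome:
    """With probability ``mutation_rate``, perturb one coordinate.

    A delta drawn uniformly from +/- ``mutation_scale`` is added to one
    coordinate (clipped to keep it in [0, 1]) and the remaining
    coordinates are rescaled so the sum returns to 1; for K=2 this reduces
    to the complementary update (a+d, b-d).  At a vertex (the other
    coordinates sum to 0) the deficit is spread equally instead.
    """
    w = c.weights.copy()
    if rng.random() >= config.mutation_rate:
        return Chromosome(w)
    k = w.size
    i = int(rng.integers(k))
    delta = rng.uniform(-config.mutation_scale, config.mutation_scale)
    new_wi = float(np.clip(w[i] + delta, 0.0, 1.0))
    others = np.arange(k) != i
    rest = w[others].sum()
    if rest > 0.0:
        w[others] *= (1.0 - new_wi) / rest
    else:
        w[others] = (1.0 - new_wi) / (k - 1)
    w[i] = new_wi
    return Chromosome(w)


def _elite_indices(population: list[Chromosome], n: int) -> list[int]:
    # stable sort: among equal fitnesses the earlier-evaluated chromosome ranks first
    order = sorted(range(len(population)), key=lambda i: -population[i].fitness)
    return order[:n]


def optimize(bundle: ModelBundle, config: GAConfig | None = None) -> OptimizationResult:
    """Run the generational GA and return the best weights found.

    The best chromosome is tracked across all evaluations with strict
    improvement only, so among equal-fitness chromosomes the earliest
    evaluated wins — runs are fully reproducible from ``config.seed``.
    With ``elitism >= 1`` the per-generation best-fitness trace is
    non-decreasing.  Terminates after ``max_generations`` generations or
    as soon as the best fitness reaches ``fitness_target``.
    """
    if config is None:
        config = GAConfig()
    if bundle.labels is None:
        raise ValidationError("optimize needs a bundle with ground-truth labels")
    rng = np.random.default_rng(config.seed)
    stacked = bundle.stacked()
    labels = bundle.labels.labels
    k = bundle.n_models

    population = init_population(k, config, rng)
    for c in population:
        c.fitness = _ensemble_accuracy(c.weights, stacked, labels)

    best = population[0]
    for c in population[1:]:
        if c.fitness > best.fitness:
            best = c
    fitness_trace = [best.fitness]
    mean_trace = [float(np.mean([c.fitness for c in population]))]

    termination = "max_generations"
    generations_run = 0
    target = config.fitness_target
    if target is not None and best.fitness >= target:
        termination = "fitness_target"
    else:
        for gen in range(1, config.max_generations + 1):
            new_pop = [
                Chromosome(population[i].weights.copy(), population[i].fitness)
                for i in _elite_indices(population, config.elitism)
            ]
            while len(new_pop) < config.population_size:
                parent1 = select(population, config, rng)
                parent2 = select(population, config, rng)
                if rng.random() < config.crossover_rate:
                    child1, child2 = crossover(parent1, parent2, rng)
                else:
                    child1 = Chromosome(parent1.weights.copy())
                    child2 = Chromosome(parent2.weights.copy())
                for child in (child1, child2):
                    if len(new_pop) < config.population_size:
                        new_pop.append(mutate(child, config, rng))
            population = new_pop
            for c in population:
                if c.fitness is None:
                    c.fitness = _ensemble_accuracy(c.weights, stacked, labels)
                    if c.fitness > best.fitness:
                        best = c
            generations_run = gen
            fitness_trace.append(best.fitness)
            mean_trace.append(float(np.mean([c.fitness for c in population])))
            if target is not None and best.fitness >= target:
                termination = "fitness_target"
                break

    return OptimizationResult(
        best_weights=WeightVector(best.weights.copy(), bundle.model_names),
        best_fitness=float(best.fitness),
        fitness_trace=tuple(fitness_trace),
        mean_trace=tuple(mean_trace),
        generations_run=generations_run,
        termination=termination,
        seed=config.seed,
    )


def grid_search_oracle(bundle: ModelBundle, step: float = 0.01) -> tuple[WeightVector, float]:
    """Exhaustive fitness evaluation on a regular simplex grid (K = 2 or 3).

    ``step`` is rounded to the nearest 1/M so grid points are exact
    multiples of 1/M.  Ties are broken toward the lexicographically
    smallest weight vector; the result is exact and deterministic, which
    is what makes it a useful independent check on the GA.
    """
    if bundle.labels is None:
        raise ValidationError("grid search needs a bundle with ground-truth labels")
    k = bundle.n_models
    if k not in (2, 3):
        raise ValidationError(f"grid search supports K=2 or K=3 only, got K={k}")
    if not 0.0 < step <= 0.5:
        raise ValidationError(f"step must be in (0, 0.5], got {step}")
    m = int(round(1.0 / step))
    stacked = bundle.stacked()
    labels = bundle.labels.labels

    best_w: np.ndarray | None = None
    best_fit = -1.0
    if k == 2:
        candidates = ((i, m - i) for i in range(m + 1))
    else:
        candidates = ((i, j, m - i - j) for i in range(m + 1) for j in range(m - i + 1))
    for parts in candidates:
        w = np.asarray(parts, dtype=float) / m
        fit = _ensemble_accuracy(w, stacked, labels)
        if fit > best_fit:
            best_fit, best_w = fit, w
    return WeightVector(best_w, bundle.model_names), best_fit
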