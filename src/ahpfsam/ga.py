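"""Genetic-algorithm optimization of the fuzzy rule structure.

Sits between the fuzzy c-means initialization and the gradient-descent
tuning: a population of candidate rule bases (one per FCM run with varying
cluster count) evolves under roulette selection, 1-point crossover on rule
boundaries and bit/parameter mutation. The fitness trades training error
against rule-base size,

    fit(m) = ln(sigma_bar^2) + m * ln(n) / n

(lower is better), a per-sample MDL/BIC-style penalty that pressures the
population toward fewer rules while fitting the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fsam import (
    FSAMModel,
    FuzzyRule,
    WIDTH_FLOOR_FRACTION,
    POSITIVE_FLOOR,
    fcm_initialize,
    predict_batch,
)

__all__ = [
    "Chromosome",
    "GAConfig",
    "fitness",
    "rule_count_penalty",
    "initial_population",
    "roulette_select",
    "crossover_1point",
    "mutate",
    "evolve",
]

MSE_FLOOR = 1e-12


@dataclass(frozen=True)
class RuleBlock:
    """One chromosome segment: an activation bit plus full rule parameters."""

    active: bool
    centers: np.ndarray
    widths: np.ndarray
    centroid: float
    volume: float
    weight: float


@dataclass(frozen=True)
class Chromosome:
    """Variable-length string of rule blocks; decodes to an FSAMModel."""

    blocks: tuple[RuleBlock, ...]
    threshold: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not any(b.active for b in self.blocks):
            raise ValueError("chromosome needs >=1 active block")

    @property
    def n_active(self) -> int:
        return sum(b.active for b in self.blocks)

    def decode(self) -> FSAMModel:
        rules = tuple(
            FuzzyRule(b.centers, b.widths, b.centroid, b.volume, b.weight)
            for b in self.blocks
            if b.active
        )
        return FSAMModel(rules, threshold=self.threshold)

    @staticmethod
    def from_model(model: FSAMModel) -> "Chromosome":
        blocks = tuple(
            RuleBlock(True, r.centers, r.widths, r.centroid, r.volume, r.weight)
            for r in model.rules
        )
        return Chromosome(blocks, threshold=model.threshold)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    elitism_count: int = 1
    c_min: int = 2
    c_max: int = 15
    fuzzifier: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be < population_size")
        if not 1 <= self.c_min <= self.c_max:
            raise ValueError("need 1 <= c_min <= c_max")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def rule_count_penalty(m: int, n: int) -> float:
    """Complexity term m * ln(n) / n; strictly increasing in m."""
    return m * np.log(n) / n


def fitness(
    model: FSAMModel, X, y, penalty=rule_count_penalty
) -> float:
    """fit = ln(mean squared error) + penalty(m, n); lower is better.

    The MSE is floored at 1e-12 so a perfect fit has a finite, comparable
    fitness dominated by the complexity term.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("fitness needs >=2 samples")
    mse = float(np.mean((predict_batch(model, X) - y) ** 2))
    return float(np.log(max(mse, MSE_FLOOR)) + penalty(model.n_rules, y.size))


def initial_population(
    X, y, cfg: GAConfig, max_retries: int = 5
) -> list[Chromosome]:
    """One chromosome per FCM run, cluster counts uniform on [c_min, c_max].

    Each individual gets a distinct seed derived from the master seed, so
    the population is reproducible yet diverse. A failed FCM run (e.g.
    cluster count above the sample count) is re-drawn a bounded number of
    times with a smaller count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    population = []
    for i in range(cfg.population_size):
        c_hi = min(cfg.c_max, len(y))
        c = int(rng.integers(cfg.c_min, c_hi + 1))
        for attempt in range(max_retries):
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                model = fcm_initialize(
                    X, y, n_clusters=c, fuzzifier=cfg.fuzzifier, seed=seed
                )
                population.append(Chromosome.from_model(model))
                break
            except ValueError:
                c = max(cfg.c_min, c - 1)
        else:
            raise RuntimeError(f"FCM initialization failed for individual {i}")
    return population


def roulette_select(population, fitnesses, rng) -> tuple[Chromosome, Chromosome]:
    """Fitness-proportionate parent sampling (minimization transform).

    Selection mass g_k = (max fit − fit_k) + δ with δ = 1e-6·spread, so
    the best (lowest-fit) individual gets the biggest wheel slice; equal
    fitnesses degrade to uniform sampling.
    """
    fit = np.asarray(fitnesses, dtype=float)
    spread = fit.max() - fit.min()
    if spread <= 0:
        probs = np.full(fit.size, 1.0 / fit.size)
    else:
        g = (fit.max() - fit) + 1e-6 * spread
        probs = g / g.sum()
    i, j = rng.choice(fit.size, size=2, p=probs)
    return population[i], population[j]


def crossover_1point(
    a: Chromosome, b: Chromosome, rng
) -> tuple[Chromosome, Chromosome]:
    """Swap tails at a cut on rule-block boundaries.

    The cut position is uniform on [0, min(len_a, len_b)]; offspring may
    have different lengths than their parents but the total block count
    of the pair is conserved. Offspring with no active block are repaired
    by reactivating one random block.
    """
    cut = int(rng.integers(0, min(len(a.blocks), len(b.blocks)) + 1))
    child1 = a.blocks[:cut] + b.blocks[cut:]
    child2 = b.blocks[:cut] + a.blocks[cut:]
    return (
        _repair(child1, a.threshold, rng),
        _repair(child2, b.threshold, rng),
    )


def _repair(blocks, threshold, rng) -> Chromosome:
    blocks = tuple(blocks)
    if not any(b.active for b in blocks):
        k = int(rng.integers(0, len(blocks)))
        blocks = tuple(
            replace(b, active=True) if i == k else b
            for i, b in enumerate(blocks)
        )
    return Chromosome(blocks, threshold=threshold)


def mutate(
    chrom: Chromosome, cfg: GAConfig, rng, data_ranges, output_range=1.0
) -> Chromosome:
    """Bit-flip activation bits and jitter real parameters.

    Each active bit flips with probability ``mutation_rate`` (this is how
    the rule count moves); each real parameter is perturbed with the same
    probability by Gaussian noise with sigma = 5% of its data-derived
    range. Constraints are re-floored and >=1 active block is restored.
    """
    data_ranges = np.asarray(data_ranges, dtype=float)
    scale = np.where(data_ranges > 0, data_ranges, 1.0)
    out_scale = output_range if output_range > 0 else 1.0
    floor = WIDTH_FLOOR_FRACTION * scale
    rate = cfg.mutation_rate
    new_blocks = []
    for b in chrom.blocks:
        active = b.active ^ bool(rng.random() < rate)
        centers = b.centers.copy()
        widths = b.widths.copy()
        hit = rng.random(centers.size) < rate
        centers[hit] += rng.normal(0, 0.05 * scale[hit])
        hit = rng.random(widths.size) < rate
        widths[hit] += rng.normal(0, 0.05 * scale[hit])
        widths = np.maximum(widths, floor)
        centroid = b.centroid
        if rng.random() < rate:
            centroid += rng.normal(0, 0.05 * out_scale)
        volume = b.volume
        if rng.random() < rate:
            volume = max(volume + rng.normal(0, 0.05), POSITIVE_FLOOR)
        weight = b.weight
        if rng.random() < rate:
            weight = max(weight + rng.normal(0, 0.05), POSITIVE_FLOOR)
        new_blocks.append(
            RuleBlock(active, centers, widths, centroid, volume, weight)
        )
    return _repair(new_blocks, chrom.threshold, rng)


@dataclass(frozen=True)
class GAResult:
    best_model: FSAMModel
    best_fitness: float
    history: list  # (generation, best_fit, mean_fit, best_rule_count)
    initial_mean_rules: float = field(default=0.0)


def evolve(X, y, cfg: GAConfig, penalty=rule_count_penalty) -> GAResult:
    """Generational GA over rule bases; returns the best-ever decoded model.

    Elitism copies the ``elitism_count`` best individuals unchanged, which
    makes the best-fitness trace monotonically non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6A]))
    population = initial_population(X, y, cfg)
    data_ranges = np.ptp(X, axis=0)
    out_range = float(np.ptp(y)) or 1.0

    def evaluate(pop):
        return np.array([fitness(c.decode(), X, y, penalty) for c in pop])

    fits = evaluate(population)
    initial_mean_rules = float(np.mean([c.n_active for c in population]))
    best_idx = int(np.argmin(fits))
    best_chrom, best_fit = population[best_idx], float(fits[best_idx])
    history = []
    for gen in range(cfg.generations):
        order = np.argsort(fits, kind="stable")
        elite = [population[i] for i in order[: cfg.elitism_count]]
        offspring = list(elite)
        while len(offspring) < cfg.population_size:
            pa, pb = roulette_select(population, fits, rng)
            if rng.random() < cfg.crossover_rate:
                ca, cb = crossover_1point(pa, pb, rng)
            else:
                ca, cb = pa, pb
            offspring.append(mutate(ca, cfg, rng, data_ranges, out_range))
            if len(offspring) < cfg.population_size:
                offspring.append(mutate(cb, cfg, rng, data_ranges, out_range))
        population = offspring
        fits = evaluate(population)
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_chrom, best_fit = population[gen_best], float(fits[gen_best])
        history.append(
            (gen, best_fit, float(fits.mean()), best_chrom.n_active)
        )
    return GAResult(
        best_model=best_chrom.decode(),
        best_fitness=best_fit,
        history=history,
        initial_mean_rules=initial_mean_rules,
    )
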