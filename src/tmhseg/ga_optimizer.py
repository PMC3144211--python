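"""Piecewise-threshold optimization with a customized genetic algorithm.

A fixed threshold cannot separate helices joined by very short loops and
helices separated by long loops at the same time.  The search object is
therefore a *piecewise-constant threshold profile* along the sequence,
encoded as a chromosome: an ordered list of genes ``(t, u)`` where the
threshold ``t`` applies from the previous gene's boundary (exclusive)
through position ``u`` (inclusive), and the last ``u`` equals the sequence
length.  Fitness is the residue-level accuracy Q_AA of the labels the
chromosome induces on the fused profile.

The operators are tailored to the encoding: a one-cut crossover that cuts
the second parent at its first boundary beyond the first parent's cut (so
children inherit a consistent left/right split of the sequence), and a
mutation that perturbs either a gene's threshold or its boundary.  Elitism
clones the fittest chromosomes into the next generation, which makes the
best-so-far fitness non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import Interval
from .profiling import ResidueProfile
from .segmentation import call_residues, segments_to_labels

Gene = Tuple[float, int]


@dataclass(frozen=True)
class ThresholdChromosome:
    """Ordered genes ``(t, u)`` encoding a piecewise threshold over 1..length.

    Boundaries ``u`` are strictly increasing and the last equals ``length``;
    gene k's threshold applies to positions u_{k-1}+1 .. u_k.
    """

    genes: Tuple[Gene, ...]
    length: int

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("chromosome needs at least one gene")
        prev = 0
        for t, u in self.genes:
            if not (prev < u <= self.length):
                raise ValueError(f"boundaries must be strictly increasing in 1..{self.length}")
            prev = u
        if self.genes[-1][1] != self.length:
            raise ValueError("last gene must end at the sequence length")

    def thresholds(self) -> np.ndarray:
        """Per-position threshold vector (index 0 = position 1)."""
        bounds = [u for _, u in self.genes]
        widths = np.diff([0] + bounds)
        return np.repeat([t for t, _ in self.genes], widths)


def threshold_at(chromosome: ThresholdChromosome, position: int) -> float:
    """Threshold applying at a 1-based position: first gene with u >= position."""
    if not (1 <= position <= chromosome.length):
        raise ValueError(f"position {position} out of range 1..{chromosome.length}")
    for t, u in chromosome.genes:
        if u >= position:
            return t
    raise AssertionError("unreachable: last boundary equals length")


@dataclass
class GAConfig:
    """GA hyper-parameters.

    ``threshold_range``, ``mutation_step`` and ``boundary_step`` default to
    profile-derived values at run time (range = fused min/max padded by 5%,
    step = 10% of the range width, boundary step = ceil(L/20)).  Setting
    ``threshold_grid``/``boundary_grid`` restricts thresholds and internal
    boundaries to finite sets, which makes the search space enumerable.
    """

    population_size: int = 50
    generations: int = 100
    p_crossover: float = 0.8
    p_mutation: float = 0.1
    elite_count: int = 2
    genes_init: int = 2
    threshold_range: Optional[Tuple[float, float]] = None
    mutation_step: Optional[float] = None
    boundary_step: Optional[int] = None
    threshold_grid: Optional[Sequence[float]] = None
    boundary_grid: Optional[Sequence[int]] = None
    stall_generations: Optional[int] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class GAResult:
    best_chromosome: ThresholdChromosome
    best_fitness: float
    fitness_history: List[float] = field(default_factory=list)


def _repair(genes: Sequence[Gene], length: int) -> ThresholdChromosome:
    """Restore chromosome invariants after crossover: drop genes whose
    boundary does not advance, and extend the last gene to the length."""
    cleaned: List[Gene] = []
    prev = 0
    for t, u in genes:
        if u > prev:
            cleaned.append((t, min(u, length)))
            prev = cleaned[-1][1]
    if not cleaned:
        cleaned = [(0.0, length)]
    if cleaned[-1][1] != length:
        cleaned[-1] = (cleaned[-1][0], length)
    return ThresholdChromosome(tuple(cleaned), length)


def one_cut_crossover(
    parent_a: ThresholdChromosome,
    parent_b: ThresholdChromosome,
    rng: np.random.Generator,
) -> Tuple[ThresholdChromosome, ThresholdChromosome]:
    """Cut parent A after a random gene; cut parent B before its first gene
    whose boundary exceeds A's cut boundary; swap the suffixes."""
    if parent_a.length != parent_b.length:
        raise ValueError("parents must encode the same sequence length")
    q = int(rng.integers(1, len(parent_a.genes) + 1))
    u_q = parent_a.genes[q - 1][1]
    idx_b = next((i for i, (_, u) in enumerate(parent_b.genes) if u > u_q), len(parent_b.genes))
    child_a = _repair(parent_a.genes[:q] + parent_b.genes[idx_b:], parent_a.length)
    child_b = _repair(parent_b.genes[:idx_b] + parent_a.genes[q:], parent_a.length)
    return child_a, child_b


def mutate(
    chromosome: ThresholdChromosome,
    config: GAConfig,
    rng: np.random.Generator,
) -> ThresholdChromosome:
    """Mutate each gene independently with probability ``p_mutation``.

    A mutated gene either shifts its threshold by up to ``mutation_step``
    (clamped to ``threshold_range``, or resampled from ``threshold_grid``)
    or moves its boundary by up to ``boundary_step`` positions, clamped
    strictly between the neighbouring boundaries.  The last boundary is
    pinned to the sequence length and only its threshold can mutate.
    """
    lo, hi = config.threshold_range if config.threshold_range else (-math.inf, math.inf)
    step = config.mutation_step if config.mutation_step is not None else 1.0
    bstep = config.boundary_step if config.boundary_step is not None else max(1, chromosome.length // 20)

    genes = list(chromosome.genes)
    for i, (t, u) in enumerate(genes):
        if rng.random() >= config.p_mutation:
            continue
        is_last = i == len(genes) - 1
        mutate_threshold = is_last or rng.integers(2) == 0
        if mutate_threshold:
            if config.threshold_grid is not None:
                grid = list(config.threshold_grid)
                t = float(grid[int(rng.integers(len(grid)))])
            else:
                delta = step * (1.0 - rng.random())  # in (0, step]
                sign = 1.0 if rng.integers(2) == 0 else -1.0
                t = float(min(max(t + sign * delta, lo), hi))
        else:
            prev_u = genes[i - 1][1] if i > 0 else 0
            next_u = genes[i + 1][1]
            low, high = prev_u + 1, next_u - 1
            if low > high:
                continue
            if config.boundary_grid is not None:
                options = [g for g in config.boundary_grid if low <= g <= high and g != u]
                if not options:
                    continue
                u = int(options[int(rng.integers(len(options)))])
            else:
                delta = int(rng.integers(1, bstep + 1))
                sign = 1 if rng.integers(2) == 0 else -1
                u = int(min(max(u + sign * delta, low), high))
        genes[i] = (t, u)
    return ThresholdChromosome(tuple(genes), chromosome.length)


def fitness(
    chromosome: ThresholdChromosome,
    profile: ResidueProfile,
    reference_segments: Sequence[Interval],
) -> float:
    """Residue-level accuracy Q_AA of the labels this chromosome induces."""
    if reference_segments is None:
        raise ValueError("fitness needs reference segments")
    predicted = call_residues(profile, chromosome)
    truth = segments_to_labels(reference_segments, len(profile))
    return float(np.mean(predicted == truth))


def _equal_width_boundaries(length: int, k: int) -> List[int]:
    bounds = []
    prev = 0
    for i in range(1, k + 1):
        u = max(prev + 1, round(i * length / k))
        if u > length:
            break
        bounds.append(u)
        prev = u
    bounds[-1] = length
    return bounds


def _random_chromosome(length: int, config: GAConfig, lo: float, hi: float, rng: np.random.Generator) -> ThresholdChromosome:
    def _draw_t() -> float:
        if config.threshold_grid is not None:
            grid = list(config.threshold_grid)
            return float(grid[int(rng.integers(len(grid)))])
        return float(rng.uniform(lo, hi))

    k = max(1, config.genes_init)
    if config.boundary_grid is not None:
        internal = sorted({int(b) for b in config.boundary_grid if 1 <= b < length})
        if len(internal) > k - 1:
            chosen = rng.choice(len(internal), size=k - 1, replace=False)
            internal = sorted(internal[i] for i in chosen)
        bounds = internal + [length]
    else:
        bounds = _equal_width_boundaries(length, min(k, length))
    genes = tuple((_draw_t(), u) for u in bounds)
    return ThresholdChromosome(genes, length)


def _roulette(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    total = fitnesses.sum()
    if total <= 0:
        return int(rng.integers(len(fitnesses)))
    return int(rng.choice(len(fitnesses), p=fitnesses / total))


def run_ga(
    profile: ResidueProfile,
    reference_segments: Sequence[Interval],
    config: Optional[GAConfig] = None,
) -> GAResult:
    """Generational GA: roulette selection, one-cut crossover, gene mutation,
    elitism.  Deterministic given ``config.rng_seed``.

    The initial population always contains the single-gene chromosome at
    threshold 0 (the fixed-threshold baseline), so the result is never worse
    than that baseline.
    """
    config = config or GAConfig()
    if config.population_size < 2:
        raise ValueError("population_size must be >= 2")
    rng = np.random.default_rng(config.rng_seed)
    length = len(profile)

    if config.threshold_range is not None:
        lo, hi = config.threshold_range
    else:
        fmin, fmax = float(profile.fused.min()), float(profile.fused.max())
        pad = 0.05 * (fmax - fmin) if fmax > fmin else 1.0
        lo, hi = fmin - pad, fmax + pad
    resolved = replace(
        config,
        threshold_range=(lo, hi),
        mutation_step=config.mutation_step if config.mutation_step is not None else 0.1 * (hi - lo),
        boundary_step=config.boundary_step if config.boundary_step is not None else math.ceil(length / 20),
    )

    baseline_t = 0.0
    if config.threshold_grid is not None:
        grid = list(config.threshold_grid)
        baseline_t = float(min(grid, key=lambda g: abs(g)))
    population = [ThresholdChromosome(((baseline_t, length),), length)]
    while len(population) < resolved.population_size:
        population.append(_random_chromosome(length, resolved, lo, hi, rng))

    def _evaluate(pop: List[ThresholdChromosome]) -> np.ndarray:
        return np.array([fitness(c, profile, reference_segments) for c in pop])

    fits = _evaluate(population)
    best_idx = int(fits.argmax())
    best_chrom, best_fit = population[best_idx], float(fits[best_idx])
    history = [best_fit]
    stall = 0

    for _ in range(resolved.generations):
        order = np.argsort(fits)[::-1]
        next_pop = [population[i] for i in order[: resolved.elite_count]]
        while len(next_pop) < resolved.population_size:
            pa = population[_roulette(fits, rng)]
            pb = population[_roulette(fits, rng)]
            if rng.random() < resolved.p_crossover:
                ca, cb = one_cut_crossover(pa, pb, rng)
            else:
                ca, cb = pa, pb
            next_pop.append(mutate(ca, resolved, rng))
            if len(next_pop) < resolved.population_size:
                next_pop.append(mutate(cb, resolved, rng))
        population = next_pop
        fits = _evaluate(population)
        gen_best = int(fits.argmax())
        if float(fits[gen_best]) > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = population[gen_best]
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if resolved.stall_generations is not None and stall >= resolved.stall_generations:
            break
        if best_fit >= 1.0:
            break

    return GAResult(best_chromosome=best_chrom, best_fitness=best_fit, fitness_history=history)


def scale_chromosome(template: ThresholdChromosome, length: int) -> ThresholdChromosome:
    """Rescale a template's boundaries proportionally to a new length."""
    genes: List[Gene] = []
    prev = 0
    for t, u in template.genes:
        scaled = max(prev + 1, round(u * length / template.length))
        if scaled > length:
            break
        genes.append((t, scaled))
        prev = scaled
    if not genes:
        genes = [(template.genes[-1][0], length)]
    genes[-1] = (genes[-1][0], length)
    return ThresholdChromosome(tuple(genes), length)


def fit_threshold_template(
    profiles: Sequence[ResidueProfile],
    references: Sequence[Sequence[Interval]],
    config: Optional[GAConfig] = None,
    template_length: int = 100,
) -> GAResult:
    """Training-mode GA: one shared threshold template for many proteins.

    The template lives on a virtual sequence of ``template_length``
    positions and is rescaled to each protein; fitness is the mean Q_AA over
    the training proteins.  Unlike per-protein refinement this is usable on
    proteins whose annotation is unknown.
    """
    if len(profiles) != len(references) or not profiles:
        raise ValueError("profiles and references must be non-empty and aligned")
    config = config or GAConfig()
    rng = np.random.default_rng(config.rng_seed)
    all_fused = np.concatenate([p.fused for p in profiles])
    if config.threshold_range is not None:
        lo, hi = config.threshold_range
    else:
        fmin, fmax = float(all_fused.min()), float(all_fused.max())
        pad = 0.05 * (fmax - fmin) if fmax > fmin else 1.0
        lo, hi = fmin - pad, fmax + pad
    resolved = replace(
        config,
        threshold_range=(lo, hi),
        mutation_step=config.mutation_step if config.mutation_step is not None else 0.1 * (hi - lo),
        boundary_step=config.boundary_step if config.boundary_step is not None else math.ceil(template_length / 20),
    )

    def template_fitness(chrom: ThresholdChromosome) -> float:
        vals = []
        for prof, ref in zip(profiles, references):
            scaled = scale_chromosome(chrom, len(prof))
            vals.append(fitness(scaled, prof, ref))
        return float(np.mean(vals))

    population = [ThresholdChromosome(((0.0, template_length),), template_length)]
    while len(population) < resolved.population_size:
        population.append(_random_chromosome(template_length, resolved, lo, hi, rng))

    fits = np.array([template_fitness(c) for c in population])
    best_idx = int(fits.argmax())
    best_chrom, best_fit = population[best_idx], float(fits[best_idx])
    history = [best_fit]
    stall = 0
    for _ in range(resolved.generations):
        order = np.argsort(fits)[::-1]
        next_pop = [population[i] for i in order[: resolved.elite_count]]
        while len(next_pop) < resolved.population_size:
            pa = population[_roulette(fits, rng)]
            pb = population[_roulette(fits, rng)]
            if rng.random() < resolved.p_crossover:
                ca, cb = one_cut_crossover(pa, pb, rng)
            else:
                ca, cb = pa, pb
            next_pop.append(mutate(ca, resolved, rng))
            if len(next_pop) < resolved.population_size:
                next_pop.append(mutate(cb, resolved, rng))
        population = next_pop
        fits = np.array([template_fitness(c) for c in population])
        gen_best = int(fits.argmax())
        if float(fits[gen_best]) > best_fit:
            best_fit, best_chrom, stall = float(fits[gen_best]), population[gen_best], 0
        else:
            stall += 1
        history.append(best_fit)
        if resolved.stall_generations is not None and stall >= resolved.stall_generations:
            break
    return GAResult(best_chromosome=best_chrom, best_fitness=best_fit, fitness_history=history)
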