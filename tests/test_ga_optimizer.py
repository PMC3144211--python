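import numpy as np
import pytest

from tmhseg.ga_optimizer import (
    GAConfig,
    ThresholdChromosome,
    fit_threshold_template,
    fitness,
    mutate,
    one_cut_crossover,
    run_ga,
    scale_chromosome,
    threshold_at,
)
from tmhseg.profiling import build_profile
from tmhseg.segmentation import segments_to_labels


def make_profile(fused, pid="p"):
    fused = np.asarray(fused, dtype=float)
    return build_profile(pid, fused, w_min=1, w_max=1)


def random_chromosome(rng, length):
    n_genes = int(rng.integers(1, 6))
    bounds = sorted(rng.choice(np.arange(1, length), size=min(n_genes - 1, length - 1), replace=False).tolist()) + [length]
    return ThresholdChromosome(tuple((float(rng.normal()), int(u)) for u in bounds), length)


class TestChromosome:
    def test_threshold_at_segments(self):
        chrom = ThresholdChromosome(((0.5, 10), (-0.2, 30)), 30)
        assert threshold_at(chrom, 1) == 0.5
        assert threshold_at(chrom, 10) == 0.5
        assert threshold_at(chrom, 11) == -0.2
        assert threshold_at(chrom, 30) == -0.2

    def test_single_gene_covers_everything(self):
        chrom = ThresholdChromosome(((0.0, 7),), 7)
        assert all(threshold_at(chrom, p) == 0.0 for p in range(1, 8))

    def test_out_of_range_position_is_error(self):
        chrom = ThresholdChromosome(((0.0, 5),), 5)
        with pytest.raises(ValueError):
            threshold_at(chrom, 0)
        with pytest.raises(ValueError):
            threshold_at(chrom, 6)

    def test_thresholds_vector_matches_positional_lookup(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            chrom = random_chromosome(rng, int(rng.integers(2, 40)))
            vec = chrom.thresholds()
            assert vec.shape == (chrom.length,)
            for p in range(1, chrom.length + 1):
                assert vec[p - 1] == threshold_at(chrom, p)

    @pytest.mark.parametrize(
        "genes,length",
        [((), 5), (((0.0, 3),), 5), (((0.0, 3), (1.0, 3)), 3), (((0.0, 0),), 3)],
    )
    def test_invalid_chromosomes_rejected(self, genes, length):
        with pytest.raises(ValueError):
            ThresholdChromosome(tuple(genes), length)


class _FixedCut:
    """Stub RNG forcing the crossover cut after gene q."""

    def __init__(self, q):
        self.q = q

    def integers(self, low, high=None):
        return self.q


class TestCrossover:
    def test_hand_traced_example(self):
        a = ThresholdChromosome(((0.2, 10), (0.5, 50)), 50)
        b = ThresholdChromosome(((0.0, 15), (0.3, 50)), 50)
        child_a, child_b = one_cut_crossover(a, b, _FixedCut(1))
        assert child_a.genes == ((0.2, 10), (0.0, 15), (0.3, 50))
        assert child_b.genes == ((0.5, 50),)

    def test_self_crossover_is_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            chrom = random_chromosome(rng, int(rng.integers(2, 30)))
            ca, cb = one_cut_crossover(chrom, chrom, rng)
            assert ca.genes == chrom.genes and cb.genes == chrom.genes

    def test_children_always_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            length = int(rng.integers(2, 40))
            a, b = random_chromosome(rng, length), random_chromosome(rng, length)
            for child in one_cut_crossover(a, b, rng):
                assert child.genes[-1][1] == length  # revalidated by constructor

    def test_length_mismatch_is_error(self):
        a = ThresholdChromosome(((0.0, 5),), 5)
        b = ThresholdChromosome(((0.0, 6),), 6)
        with pytest.raises(ValueError):
            one_cut_crossover(a, b, np.random.default_rng(0))


class TestMutate:
    def test_zero_probability_is_identity(self):
        rng = np.random.default_rng(0)
        chrom = random_chromosome(rng, 25)
        out = mutate(chrom, GAConfig(p_mutation=0.0), rng)
        assert out.genes == chrom.genes

    def test_thresholds_stay_in_range(self):
        rng = np.random.default_rng(3)
        config = GAConfig(p_mutation=1.0, threshold_range=(-1.0, 1.0), mutation_step=5.0, boundary_step=3)
        for _ in range(200):
            chrom = random_chromosome(rng, 20)
            out = mutate(chrom, config, rng)
            for (t, _), (t0, _) in zip(out.genes, chrom.genes):
                assert -1.0 <= t <= 1.0 or t == t0  # unchanged thresholds may predate the range

    def test_boundaries_clamped_and_last_pinned(self):
        rng = np.random.default_rng(4)
        config = GAConfig(p_mutation=1.0, threshold_range=(-1, 1), mutation_step=0.1, boundary_step=50)
        for _ in range(500):
            length = int(rng.integers(2, 15))
            chrom = random_chromosome(rng, length)
            out = mutate(chrom, config, rng)
            assert out.genes[-1][1] == length  # constructor enforces ordering too

    def test_grid_mutation_stays_on_grid(self):
        rng = np.random.default_rng(5)
        grid_t, grid_u = [-1.0, 0.0, 1.0], [5, 10, 15]
        config = GAConfig(p_mutation=1.0, threshold_grid=grid_t, boundary_grid=grid_u)
        chrom = ThresholdChromosome(((0.0, 10), (0.0, 20)), 20)
        for _ in range(100):
            chrom = mutate(chrom, config, rng)
            assert all(t in grid_t for t, _ in chrom.genes)
            assert all(u in grid_u or u == 20 for _, u in chrom.genes)


class TestFitness:
    def test_perfect_calls_score_one(self):
        profile = make_profile([-1, -1, 1, 1, -1, -1])
        chrom = ThresholdChromosome(((0.0, 6),), 6)
        assert fitness(chrom, profile, [(1, 2), (5, 6)]) == 1.0

    def test_inverted_calls_score_zero(self):
        profile = make_profile([-1, -1, 1, 1])
        chrom = ThresholdChromosome(((0.0, 4),), 4)
        assert fitness(chrom, profile, [(3, 4)]) == 0.0

    def test_half_correct(self):
        profile = make_profile([-1, -1, 1, 1])
        chrom = ThresholdChromosome(((0.0, 4),), 4)
        # truth: helix at (1,2) and (3,4) -> predicted T,T,N,N
        assert fitness(chrom, profile, [(2, 3)]) == 0.5

    def test_missing_reference_is_error(self):
        profile = make_profile([0.0])
        chrom = ThresholdChromosome(((0.0, 1),), 1)
        with pytest.raises(ValueError):
            fitness(chrom, profile, None)


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(42)
    truth = [(11, 30), (41, 55)]
    labels = segments_to_labels(truth, 70)
    fused = np.where(labels, -2.0, 1.5) + rng.normal(0, 0.8, 70)
    return make_profile(fused), truth


class TestRunGA:

    def test_same_seed_is_bit_identical(self, instance):
        profile, truth = instance
        config = GAConfig(generations=20, rng_seed=9)
        r1 = run_ga(profile, truth, config)
        r2 = run_ga(profile, truth, config)
        assert r1.best_chromosome.genes == r2.best_chromosome.genes
        assert r1.fitness_history == r2.fitness_history

    def test_history_non_decreasing_and_ends_at_best(self, instance):
        profile, truth = instance
        result = run_ga(profile, truth, GAConfig(generations=30, rng_seed=2))
        hist = result.fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))
        assert result.best_fitness == hist[-1]

    def test_never_worse_than_fixed_threshold_baseline(self, instance):
        profile, truth = instance
        baseline = fitness(ThresholdChromosome(((0.0, 70),), 70), profile, truth)
        for seed in range(5):
            result = run_ga(profile, truth, GAConfig(generations=15, rng_seed=seed))
            assert result.best_fitness >= baseline

    def test_tiny_population_is_error(self, instance):
        profile, truth = instance
        with pytest.raises(ValueError):
            run_ga(profile, truth, GAConfig(population_size=1, elite_count=0))


class TestTemplate:
    def test_scale_chromosome_preserves_structure(self):
        template = ThresholdChromosome(((0.5, 50), (-0.5, 100)), 100)
        scaled = scale_chromosome(template, 40)
        assert scaled.genes == ((0.5, 20), (-0.5, 40))

    def test_template_fit_beats_baseline_on_average(self):
        rng = np.random.default_rng(0)
        profiles, refs = [], []
        for _ in range(3):
            truth = [(21, 40)]
            labels = segments_to_labels(truth, 60)
            fused = np.where(labels, -1.0, 0.5) + rng.normal(0, 0.3, 60)
            profiles.append(make_profile(fused))
            refs.append(truth)
        config = GAConfig(population_size=20, generations=15, rng_seed=1)
        result = fit_threshold_template(profiles, refs, config)
        baselines = [
            fitness(ThresholdChromosome(((0.0, 60),), 60), p, r) for p, r in zip(profiles, refs)
        ]
        assert result.best_fitness >= np.mean(baselines)
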