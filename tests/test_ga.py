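"""Genetic algorithm: operator contracts, determinism, and oracle checks."""

import numpy as np
import pytest

from probfuse import (
    Chromosome,
    GAConfig,
    ValidationError,
    WeightVector,
    fitness,
    grid_search_oracle,
    optimize,
    predict,
    scenario_s1,
    simulate,
)
from probfuse.ga import crossover, init_population, mutate, select
from probfuse.metrics import overall_accuracy

from conftest import make_bundle, random_bundle

SIMPLEX_ATOL = 1e-9


def assert_simplex(w):
    assert w.min() >= -SIMPLEX_ATOL
    assert abs(w.sum() - 1.0) <= SIMPLEX_ATOL


class TestGAConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"elitism": 30},
            {"mutation_rate": 1.5},
            {"crossover_rate": -0.1},
            {"selection": "rank"},
            {"mutation_scale": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            GAConfig(**kwargs)


class TestInitPopulation:
    def test_all_chromosomes_on_simplex(self):
        pop = init_population(4, GAConfig(population_size=25, seed=3))
        assert len(pop) == 25
        for c in pop:
            assert_simplex(c.weights)

    def test_same_seed_gives_identical_population(self):
        cfg = GAConfig(seed=11)
        a = init_population(3, cfg)
        b = init_population(3, cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.weights, cb.weights)

    def test_baselines_precede_random_draws(self):
        pop = init_population(3, GAConfig(population_size=10, seed=0))
        np.testing.assert_array_equal(pop[0].weights, [1, 0, 0])
        np.testing.assert_array_equal(pop[1].weights, [0, 1, 0])
        np.testing.assert_array_equal(pop[2].weights, [0, 0, 1])
        np.testing.assert_allclose(pop[3].weights, 1 / 3)

    def test_single_model_rejected(self):
        with pytest.raises(ValidationError):
            init_population(1, GAConfig())


class TestFitness:
    def test_vertex_weight_equals_standalone_accuracy(self, tiny_bundle):
        for k in range(tiny_bundle.n_models):
            w = WeightVector(np.eye(2)[k], tiny_bundle.model_names)
            standalone = overall_accuracy(
                tiny_bundle.labels, predict(tiny_bundle.matrices[k])
            )
            assert fitness(w, tiny_bundle) == pytest.approx(standalone, abs=0)

    def test_identical_models_make_fitness_constant(self, rng):
        rows = rng.dirichlet(np.ones(4), size=30)
        labels = rng.integers(0, 4, size=30)
        bundle = make_bundle([rows, rows, rows], labels=labels)
        vals = {
            fitness(rng.dirichlet(np.ones(3)), bundle) for _ in range(10)
        }
        assert len(vals) == 1

    def test_labels_required(self, rng):
        bundle = random_bundle(rng, with_labels=False)
        with pytest.raises(ValidationError, match="labels"):
            fitness(np.full(3, 1 / 3), bundle)


class TestSelect:
    def _population(self, fitnesses):
        pop = [Chromosome(np.array([0.5, 0.5])) for _ in fitnesses]
        for c, f in zip(pop, fitnesses):
            c.fitness = f
        return pop

    def test_tournament_of_full_population_always_picks_fittest(self, rng):
        pop = self._population([0.2, 0.9, 0.4])
        cfg = GAConfig(selection="tournament", tournament_size=3)
        for _ in range(20):
            assert select(pop, cfg, rng).fitness == 0.9

    def test_tournament_size3_selection_probability_matches_enumeration(self, rng):
        # fitnesses (0.9, 0.1, 0.1, 0.1): the best chromosome is selected
        # unless the drawn 3-subset is {1,2,3}; P = 1 - C(3,3)/C(4,3) = 3/4
        pop = self._population([0.9, 0.1, 0.1, 0.1])
        cfg = GAConfig(selection="tournament", tournament_size=3)
        n = 4000
        wins = sum(select(pop, cfg, rng).fitness == 0.9 for _ in range(n))
        p_hat = wins / n
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(p_hat - 0.75) <= 3 * se

    def test_roulette_zero_fitness_falls_back_to_uniform(self, rng):
        pop = self._population([0.0, 0.0, 0.0])
        cfg = GAConfig(selection="roulette")
        seen = {id(select(pop, cfg, rng)) for _ in range(100)}
        assert len(seen) == 3

    def test_roulette_prefers_fit_chromosomes(self, rng):
        pop = self._population([0.9, 0.1])
        cfg = GAConfig(selection="roulette")
        n = 2000
        wins = sum(select(pop, cfg, rng).fitness == 0.9 for _ in range(n))
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(wins / n - 0.9) <= 3 * se

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValidationError):
            select([], GAConfig(), rng)


class TestCrossover:
    def test_two_model_exchange_and_renormalization(self):
        c1, c2 = crossover(Chromosome(np.array([0.8, 0.2])),
                           Chromosome(np.array([0.3, 0.7])))
        np.testing.assert_allclose(c1.weights, [8 / 15, 7 / 15], atol=1e-15)
        np.testing.assert_allclose(c2.weights, [0.6, 0.4], atol=1e-15)

    def test_identical_parents_produce_identical_offspring(self):
        p = Chromosome(np.array([0.25, 0.75]))
        c1, c2 = crossover(p, p)
        np.testing.assert_allclose(c1.weights, p.weights)
        np.testing.assert_allclose(c2.weights, p.weights)

    def test_degenerate_raw_sum_resets_to_uniform(self):
        c1, c2 = crossover(Chromosome(np.array([1.0, 0.0])),
                           Chromosome(np.array([0.0, 1.0])))
        np.testing.assert_allclose(c1.weights, [0.5, 0.5])  # raw (1, 1) normalized
        np.testing.assert_allclose(c2.weights, [0.5, 0.5])  # raw (0, 0) reset

    def test_multiway_crossover_stays_on_simplex(self, rng):
        for _ in range(200):
            k = int(rng.integers(3, 6))
            p1 = Chromosome(rng.dirichlet(np.ones(k)))
            p2 = Chromosome(rng.dirichlet(np.ones(k)))
            for child in crossover(p1, p2, rng):
                assert_simplex(child.weights)


class TestMutate:
    def test_complementary_update_for_two_weights(self, rng):
        cfg = GAConfig(mutation_rate=1.0, mutation_scale=0.05)
        c = mutate(Chromosome(np.array([0.5, 0.5])), cfg, rng)
        assert_simplex(c.weights)
        assert abs(c.weights[0] - 0.5) <= 0.05 + 1e-12

    def test_vertex_stays_valid_under_clipping(self, rng):
        cfg = GAConfig(mutation_rate=1.0, mutation_scale=0.2)
        for _ in range(100):
            c = mutate(Chromosome(np.array([1.0, 0.0])), cfg, rng)
            assert_simplex(c.weights)
            assert c.weights.min() >= 0

    def test_zero_rate_is_identity(self, rng):
        cfg = GAConfig(mutation_rate=0.0)
        w = np.array([0.3, 0.7])
        np.testing.assert_array_equal(mutate(Chromosome(w), cfg, rng).weights, w)

    def test_simplex_conserved_over_fuzzed_operations(self, rng):
        cfg = GAConfig(mutation_rate=1.0, mutation_scale=0.3)
        for _ in range(500):
            k = int(rng.integers(2, 6))
            c = mutate(Chromosome(rng.dirichlet(np.ones(k) * 0.3)), cfg, rng)
            assert_simplex(c.weights)


class TestOptimize:
    def test_flat_landscape_returns_single_model_accuracy(self, rng):
        rows = rng.dirichlet(np.ones(4), size=40)
        labels = rng.integers(0, 4, size=40)
        bundle = make_bundle([rows, rows], labels=labels)
        standalone = overall_accuracy(bundle.labels, predict(bundle.matrices[0]))
        result = optimize(bundle, GAConfig(seed=5, max_generations=10))
        assert result.best_fitness == pytest.approx(standalone, abs=0)

    def test_trace_monotone_with_elitism_and_best_is_max(self):
        bundle = simulate(scenario_s1(3))
        result = optimize(bundle, GAConfig(seed=3, elitism=1))
        trace = result.fitness_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))
        assert result.best_fitness == max(trace)
        assert result.termination == "max_generations"
        assert result.generations_run == 50

    def test_same_seed_reproduces_result_exactly(self):
        bundle = simulate(scenario_s1(9))
        r1 = optimize(bundle, GAConfig(seed=21))
        r2 = optimize(bundle, GAConfig(seed=21))
        np.testing.assert_array_equal(r1.best_weights.weights, r2.best_weights.weights)
        assert r1.fitness_trace == r2.fitness_trace
        assert r1.mean_trace == r2.mean_trace

    def test_fitness_target_stops_early(self):
        bundle = simulate(scenario_s1(2))
        result = optimize(bundle, GAConfig(seed=2, fitness_target=0.5))
        assert result.termination == "fitness_target"
        assert result.best_fitness >= 0.5
        assert result.generations_run == 0  # baselines already reach 0.5

    def test_s1_matches_grid_oracle_within_tolerance(self):
        bundle = simulate(scenario_s1(7))
        _, oracle_fit = grid_search_oracle(bundle, step=0.01)
        result = optimize(bundle, GAConfig(seed=7))
        assert result.best_fitness >= oracle_fit - 0.005

    def test_perfect_model_dominates_random_one(self):
        from probfuse import scenario_perfect_vs_random

        bundle = simulate(scenario_perfect_vs_random(11))
        result = optimize(bundle, GAConfig(seed=11))
        assert result.best_fitness == 1.0
        assert result.best_weights.weights[0] > 0.9


class TestGridSearchOracle:
    def test_step_half_enumerates_three_points_lexicographically(self, rng):
        # identical models: flat fitness, tie-break keeps the first grid
        # point, which is the lexicographically smallest (0, 1)
        rows = rng.dirichlet(np.ones(3), size=10)
        labels = rng.integers(0, 3, size=10)
        bundle = make_bundle([rows, rows], labels=labels)
        w, fit = grid_search_oracle(bundle, step=0.5)
        np.testing.assert_array_equal(w.weights, [0.0, 1.0])
        assert fit == overall_accuracy(bundle.labels, predict(bundle.matrices[0]))

    def test_oracle_interior_optimum_beats_both_standalones_on_s1(self):
        bundle = simulate(scenario_s1(7))
        accs = [
            overall_accuracy(bundle.labels, predict(m)) for m in bundle.matrices
        ]
        w, fit = grid_search_oracle(bundle, step=0.01)
        assert fit > max(accs)
        assert 0.2 <= w.weights[0] <= 0.8
        assert fitness(w, bundle) == pytest.approx(fit, abs=0)

    def test_three_model_grid(self, rng):
        bundle = random_bundle(rng, n=30, c=4, k=3)
        w, fit = grid_search_oracle(bundle, step=0.25)
        assert_simplex(w.weights)
        # oracle beats or matches every vertex
        for k in range(3):
            assert fit >= fitness(np.eye(3)[k], bundle)

    def test_unsupported_k_and_step_rejected(self, rng):
        bundle4 = random_bundle(rng, k=4)
        with pytest.raises(ValidationError, match="K=2 or K=3"):
            grid_search_oracle(bundle4, 0.1)
        bundle2 = random_bundle(rng, k=2)
        with pytest.raises(ValidationError, match="step"):
            grid_search_oracle(bundle2, 0.7)
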