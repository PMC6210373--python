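import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirselect import GAConfig, GeneticFeatureSelector, evaluate_fitness, run_ga
from nirselect.ga import (
    crossover_one_point,
    mutate_uniform,
    random_mask,
    repair_mask,
    roulette_select,
)
from nirselect.svm import SVMParams


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"pop_size": 3},
            {"pop_size": 5},
            {"p_crossover": 0.0},
            {"p_crossover": 1.5},
            {"p_mutation": 1.0},
            {"k": 0},
            {"elitism_count": 200},
        ],
    )
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            GAConfig(**bad)


class TestOperators:
    def test_roulette_degenerate_fitness(self, rng):
        idx = roulette_select(np.array([1.0, 0.0, 0.0, 0.0]), 500, rng)
        assert np.all(idx == 0)

    def test_roulette_three_to_one_ratio(self, rng):
        idx = roulette_select(np.array([3.0, 1.0]), 100_000, rng)
        assert np.isclose(np.mean(idx == 0), 0.75, atol=0.01)

    def test_roulette_uniform_on_equal_fitness(self, rng):
        idx = roulette_select(np.full(4, 0.7), 100_000, rng)
        freqs = np.bincount(idx, minlength=4) / idx.size
        assert np.allclose(freqs, 0.25, atol=0.01)

    def test_roulette_all_zero_falls_back_uniform(self, rng, caplog):
        idx = roulette_select(np.zeros(3), 30_000, rng)
        freqs = np.bincount(idx, minlength=3) / idx.size
        assert np.allclose(freqs, 1 / 3, atol=0.02)

    def test_crossover_identical_parents(self, rng):
        a = random_mask(10, 4, rng)
        c1, c2 = crossover_one_point(a, a, rng, p_crossover=1.0, k=4)
        assert np.array_equal(c1, a) and np.array_equal(c2, a)

    def test_crossover_forced_cut_and_repair(self):
        # cut after position 3 exchanges tails -> 111111 / 000000 before
        # repair; repair must restore cardinality 3
        a = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        b = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c1, c2 = crossover_one_point(a, b, rng, p_crossover=1.0, k=3)
            assert c1.sum() == 3 and c2.sum() == 3

    def test_crossover_preserves_cardinality_multiset(self, rng):
        pop = [random_mask(12, 5, rng) for _ in range(40)]
        children = []
        for i in range(0, 40, 2):
            children.extend(crossover_one_point(pop[i], pop[i + 1], rng,
                                                p_crossover=0.6, k=5))
        assert all(c.sum() == 5 for c in children)

    def test_mutation_identity_at_zero_rate(self, rng):
        m = random_mask(25, 6, rng)
        assert np.array_equal(mutate_uniform(m, rng, p_mutation=0.0, k=6), m)

    def test_mutation_rate_one_then_repair(self, rng):
        m = random_mask(25, 6, rng)
        out = mutate_uniform(m, rng, p_mutation=0.999, k=6)
        assert out.sum() == 6

    def test_expected_flip_count(self, rng):
        # 25 bits at p = 0.01 -> 0.25 expected flips per chromosome
        m = random_mask(25, 6, rng)
        flips = []
        for _ in range(10_000):
            out = mutate_uniform(m, rng, p_mutation=0.01, k=None)
            flips.append(int(np.sum(out != m)))
        mean = np.mean(flips)
        sd = np.sqrt(25 * 0.01 * 0.99 / 10_000)
        assert abs(mean - 0.25) < 3 * sd

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(4, 30), k_=st.integers(1, 30), seed=st.integers(0, 99))
    def test_repair_always_restores_cardinality(self, n, k_, seed):
        k_ = min(k_, n)
        rng = np.random.default_rng(seed)
        mask = (rng.random(n) < rng.random()).astype(np.int8)
        assert repair_mask(mask, k_, rng).sum() == k_


class TestFitness:
    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="no components"):
            evaluate_fitness(np.zeros(5), rng.standard_normal((40, 5)),
                             np.repeat(["a", "b"], 20))

    def test_class_smaller_than_folds_rejected(self, rng):
        x = rng.standard_normal((23, 4))
        y = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.raises(ValueError, match="cv_folds"):
            evaluate_fitness(np.ones(4), x, y, cv_folds=5)

    def test_deterministic_given_seed(self, small_dataset):
        from nirselect import fit_pca, split_train_test

        ds, _ = small_dataset
        model = fit_pca(ds, k=12)
        scores = model.transform(ds.absorbance)
        mask = np.r_[np.ones(6), np.zeros(6)].astype(int)
        f1 = evaluate_fitness(mask, scores, ds.labels, SVMParams(), seed=3)
        f2 = evaluate_fitness(mask, scores, ds.labels, SVMParams(), seed=3)
        assert f1 == f2

    def test_coin_flip_labels_give_chance_fitness(self, rng):
        x = rng.standard_normal((200, 6))
        y = rng.choice(["a", "b", "c", "d"], size=200)
        f = evaluate_fitness(np.ones(6), x, y, SVMParams(), seed=0)
        sd = np.sqrt(0.25 * 0.75 / 200)
        # majority-class guessing can push above 1/4; stay within a loose band
        assert f < 0.25 + 6 * sd + 0.1


def _additive_fitness(weights):
    def fn(mask):
        return float(np.dot(weights, mask))
    return fn


class TestRunGA:
    def test_elitism_monotone_best(self):
        weights = np.linspace(0.1, 1.0, 12)
        cfg = GAConfig(k=4, pop_size=20, max_generations=15, seed=5)
        _, trace = run_ga(None, None, None, cfg,
                          fitness_fn=_additive_fitness(weights), n_candidates=12)
        assert np.all(np.diff(trace.best_fitness) >= 0)

    def test_trace_reproducible(self):
        weights = np.linspace(0.1, 1.0, 10)
        cfg = GAConfig(k=3, pop_size=12, max_generations=10, seed=9)
        m1, t1 = run_ga(None, None, None, cfg,
                        fitness_fn=_additive_fitness(weights), n_candidates=10)
        m2, t2 = run_ga(None, None, None, cfg,
                        fitness_fn=_additive_fitness(weights), n_candidates=10)
        assert np.array_equal(m1, m2)
        assert np.array_equal(t1.best_fitness, t2.best_fitness)
        assert np.array_equal(t1.best_masks, t2.best_masks)

    def test_infeasible_k(self):
        cfg = GAConfig(k=11, pop_size=8, max_generations=2)
        with pytest.raises(ValueError, match="infeasible"):
            run_ga(None, None, None, cfg, fitness_fn=lambda m: 0.5,
                   n_candidates=10)

    def test_every_generation_respects_cardinality(self):
        seen = []

        def spy(mask):
            seen.append(int(mask.sum()))
            return float(mask[:3].sum())

        cfg = GAConfig(k=5, pop_size=16, max_generations=8, seed=2)
        run_ga(None, None, None, cfg, fitness_fn=spy, n_candidates=14)
        assert set(seen) == {5}

    def test_finds_exhaustive_optimum_on_additive_fitness(self):
        rng = np.random.default_rng(0)
        weights = rng.random(8)
        best_mask = None
        best_val = -np.inf
        for combo in itertools.combinations(range(8), 3):
            val = weights[list(combo)].sum()
            if val > best_val:
                best_val, best_mask = val, set(combo)
        hits = 0
        for seed in range(20):
            cfg = GAConfig(k=3, pop_size=20, max_generations=25, seed=seed)
            mask, _ = run_ga(None, None, None, cfg,
                             fitness_fn=_additive_fitness(weights),
                             n_candidates=8)
            hits += set(np.flatnonzero(mask)) == best_mask
        assert hits >= 18


class TestSelectorEstimator:
    def test_sklearn_interface(self, small_dataset):
        from nirselect import fit_pca

        ds, _ = small_dataset
        scores = fit_pca(ds, k=12).transform(ds.absorbance)
        sel = GeneticFeatureSelector(
            k=4, pop_size=12, max_generations=6, stagnation_generations=4,
            cv_folds=4, random_state=0,
        )
        out = sel.fit_transform(scores, ds.labels)
        assert out.shape == (ds.n_samples, 4)
        assert sel.support_mask_.sum() == 4
        assert sel.get_support().sum() == 4
        params = sel.get_params()
        assert params["k"] == 4 and params["random_state"] == 0
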