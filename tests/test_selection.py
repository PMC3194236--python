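import itertools

import numpy as np
import pytest

from fuzzyrules.classifier import RuleBase, evaluate
from fuzzyrules.partitions import build_vocabulary
from fuzzyrules.rules import enumerate_candidates
from fuzzyrules.selection import (
    GAConfig,
    ObjectiveWeights,
    PoolEvaluator,
    crossover,
    evolve,
    fitness,
    mutate,
    mutation_rates,
    remove_unnecessary_rules,
)


@pytest.fixture
def toy_pool(toy_dataset, vocab):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return enumerate_candidates(
            toy_dataset, vocab, max_rule_length=1,
            min_confidence=0.6, min_support=0.1, q=4,
        )


@pytest.fixture
def random_pool(random_dataset_factory, vocab):
    """A small pool over a 20-pattern random dataset (for GA oracles)."""
    import warnings

    d = random_dataset_factory(seed=42, m=20, n=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pool = enumerate_candidates(
            d, vocab, max_rule_length=2,
            min_confidence=0.55, min_support=0.05, q=10,
        )
    return pool, d


class TestObjectiveWeights:
    def test_weights_must_be_nonnegative_and_sum_to_one(self):
        ObjectiveWeights(0.5, 0.3, 0.2)
        with pytest.raises(ValueError, match="sum"):
            ObjectiveWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="nonnegative"):
            ObjectiveWeights(1.2, -0.1, -0.1)


class TestFitness:
    def test_scalarization_arithmetic(self, random_pool):
        pool, d = random_pool
        w = ObjectiveWeights(0.5, 0.3, 0.2)
        bits = np.zeros(len(pool), dtype=np.int8)
        bits[: min(3, len(pool))] = 1
        ev = PoolEvaluator(pool, d)
        nccp = ev.nccp(bits)
        nor = int(bits.sum())
        noa = sum(pool.rules[j].length for j in np.flatnonzero(bits))
        assert fitness(bits, pool, d, w) == pytest.approx(
            0.5 * nccp - 0.3 * nor - 0.2 * noa
        )

    def test_accuracy_only_weights_reduce_to_nccp(self, random_pool):
        pool, d = random_pool
        bits = np.ones(len(pool), dtype=np.int8)
        ev = PoolEvaluator(pool, d)
        assert fitness(bits, pool, d, ObjectiveWeights(1, 0, 0)) == ev.nccp(bits)

    def test_empty_subset_scores_zero(self, random_pool):
        pool, d = random_pool
        bits = np.zeros(len(pool), dtype=np.int8)
        assert fitness(bits, pool, d, ObjectiveWeights(0.5, 0.3, 0.2)) == 0.0

    def test_nccp_agrees_with_classifier_evaluate(self, random_pool, vocab):
        """The GA's fast evaluator and the classifier agree pattern by pattern."""
        pool, d = random_pool
        ev = PoolEvaluator(pool, d)
        rng = np.random.default_rng(3)
        for _ in range(10):
            bits = rng.integers(0, 2, size=len(pool)).astype(np.int8)
            if bits.sum() == 0:
                continue
            rb = RuleBase(
                rules=[pool.rules[j] for j in np.flatnonzero(bits)],
                vocabulary=vocab,
                feature_names=d.feature_names,
            )
            nccp, _ = evaluate(rb, d)
            assert ev.nccp(bits) == nccp


class TestMutationRates:
    def test_interpretability_weights_bias_toward_rule_removal(self):
        grid = [
            (a / 10, b / 10, (10 - a - b) / 10)
            for a in range(11)
            for b in range(11 - a)
        ]
        for w1, w2, w3 in grid:
            p10, p01 = mutation_rates(ObjectiveWeights(w1, w2, w3), 0.1, 0.01)
            assert 0.0 <= p01 <= p10 <= 1.0
            if w2 + w3 > 0:
                assert p10 > p01

    def test_no_interpretability_pressure_leaves_base_rate(self):
        p10, p01 = mutation_rates(ObjectiveWeights(1.0, 0.0, 0.0), 0.1, 0.01)
        assert p10 == pytest.approx(0.1)

    def test_zero_base_rates_disable_mutation(self):
        assert mutation_rates(ObjectiveWeights(0.1, 0.7, 0.2), 0.0, 0.0) == (0.0, 0.0)


class TestCrossoverAndMutation:
    def test_identical_parents_reproduce_exactly(self):
        rng = np.random.default_rng(0)
        p = np.array([1, 0, 1, 1, 0, 1], dtype=np.int8)
        for _ in range(20):
            assert np.array_equal(crossover(p, p.copy(), 1.0, rng), p)

    def test_no_crossover_copies_first_parent(self):
        rng = np.random.default_rng(0)
        a = np.array([1, 1, 1, 0], dtype=np.int8)
        b = np.array([0, 0, 0, 1], dtype=np.int8)
        assert np.array_equal(crossover(a, b, 0.0, rng), a)

    def test_child_is_two_point_recombination(self):
        """Child equals parent a outside one contiguous window and b inside."""
        rng = np.random.default_rng(7)
        a = np.ones(6, dtype=np.int8)
        b = np.zeros(6, dtype=np.int8)
        for _ in range(50):
            child = crossover(a, b, 1.0, rng)
            zeros = np.flatnonzero(child == 0)
            if zeros.size:  # the swapped-in segment must be contiguous
                assert np.array_equal(zeros, np.arange(zeros[0], zeros[-1] + 1))

    def test_certain_decay_clears_all_ones(self):
        rng = np.random.default_rng(1)
        bits = np.array([1, 0, 1, 1], dtype=np.int8)
        assert np.array_equal(
            mutate(bits, 1.0, 0.0, rng), np.zeros(4, dtype=np.int8)
        )

    def test_zero_rates_leave_string_unchanged(self):
        rng = np.random.default_rng(1)
        bits = np.array([1, 0, 1, 1], dtype=np.int8)
        assert np.array_equal(mutate(bits, 0.0, 0.0, rng), bits)

    def test_flip_count_matches_binomial_expectation(self):
        rng = np.random.default_rng(99)
        ones = np.ones(100, dtype=np.int8)
        flips = [
            100 - mutate(ones, 0.1, 0.0, rng).sum() for _ in range(10_000)
        ]
        assert np.mean(flips) == pytest.approx(10.0, abs=1.0)


class TestRemoveUnnecessaryRules:
    def test_zero_compatibility_rule_is_cleared(self, toy_dataset, vocab, toy_pool):
        # rules whose antecedent covers no training pattern can never win
        bits = np.ones(len(toy_pool), dtype=np.int8)
        cleaned = remove_unnecessary_rules(bits, toy_pool, toy_dataset)
        assert cleaned.sum() <= bits.sum()

    def test_preserves_nccp_and_never_grows(self, random_pool):
        pool, d = random_pool
        ev = PoolEvaluator(pool, d)
        rng = np.random.default_rng(5)
        for _ in range(50):
            bits = rng.integers(0, 2, size=len(pool)).astype(np.int8)
            cleaned = remove_unnecessary_rules(bits, pool, d)
            assert ev.nccp(cleaned) == ev.nccp(bits)
            assert cleaned.sum() <= bits.sum()
            assert (
                ev.lengths[cleaned.astype(bool)].sum()
                <= ev.lengths[bits.astype(bool)].sum()
            )

    def test_idempotent(self, random_pool):
        pool, d = random_pool
        rng = np.random.default_rng(6)
        bits = rng.integers(0, 2, size=len(pool)).astype(np.int8)
        once = remove_unnecessary_rules(bits, pool, d)
        twice = remove_unnecessary_rules(once, pool, d)
        assert np.array_equal(once, twice)


def exhaustive_best(pool, data, w, vocab):
    """Independent oracle: brute-force search over all rule subsets.

    Fitness is recomputed through the classifier path (per-pattern winner
    scan), not the GA's vectorized evaluator.
    """
    best = 0.0  # the empty subset
    best_complexity = (0, 0)
    for bits in itertools.product([0, 1], repeat=len(pool)):
        sel = [j for j, b in enumerate(bits) if b]
        if not sel:
            continue
        rb = RuleBase(
            rules=[pool.rules[j] for j in sel],
            vocabulary=vocab,
            feature_names=data.feature_names,
        )
        nccp, _ = evaluate(rb, data)
        nor = len(sel)
        noa = sum(pool.rules[j].length for j in sel)
        f = w.w1 * nccp - w.w2 * nor - w.w3 * noa
        if f > best or (f == best and (nor, noa) < best_complexity):
            best, best_complexity = f, (nor, noa)
    return best, best_complexity


class TestEvolve:
    def test_finds_the_perfectly_separating_pair_on_toy_data(
        self, toy_dataset, vocab
    ):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = enumerate_candidates(
                toy_dataset, vocab, max_rule_length=1,
                min_confidence=0.6, min_support=0.1, q=2,
            )
        w = ObjectiveWeights(0.5, 0.3, 0.2)
        cfg = GAConfig(n_pop=10, max_generations=20, seed=0)
        best, trace = evolve(pool, toy_dataset, w, cfg)
        oracle, _ = exhaustive_best(pool, toy_dataset, w, vocab)
        assert fitness(best, pool, toy_dataset, w) == pytest.approx(oracle)

    def test_best_fitness_trace_is_nondecreasing(self, random_pool):
        pool, d = random_pool
        _, trace = evolve(
            pool, d, ObjectiveWeights(0.5, 0.3, 0.2),
            GAConfig(n_pop=10, max_generations=30, seed=2),
        )
        assert all(
            a <= b for a, b in zip(trace.fitness, trace.fitness[1:])
        )

    def test_same_seed_reproduces_the_full_trace(self, random_pool):
        pool, d = random_pool
        w = ObjectiveWeights(0.5, 0.3, 0.2)
        cfg = GAConfig(n_pop=10, max_generations=15, seed=11)
        best1, t1 = evolve(pool, d, w, cfg)
        best2, t2 = evolve(pool, d, w, cfg)
        assert np.array_equal(best1, best2)
        assert t1.fitness == t2.fitness
        assert t1.nor == t2.nor

    def test_matches_exhaustive_search_on_small_pools(self, random_pool, vocab):
        pool, d = random_pool
        assert len(pool) <= 15
        for w in [ObjectiveWeights(0.5, 0.3, 0.2), ObjectiveWeights(0.7, 0.1, 0.2)]:
            best, _ = evolve(
                pool, d, w, GAConfig(n_pop=20, max_generations=60, seed=4)
            )
            oracle, _ = exhaustive_best(pool, d, w, vocab)
            assert fitness(best, pool, d, w) == pytest.approx(oracle)

    def test_raising_rule_count_weight_never_adds_rules(
        self, random_dataset_factory, vocab
    ):
        """Exhaustive optima: more weight on rule count, no more rules."""
        import warnings

        d = random_dataset_factory(seed=31, m=16, n=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = enumerate_candidates(
                d, vocab, max_rule_length=2,
                min_confidence=0.55, min_support=0.05, q=12,
            )
        assert len(pool) <= 12
        nors = []
        for w2 in (0.1, 0.3, 0.5):
            w = ObjectiveWeights(0.9 - w2, w2, 0.1)
            _, (nor, _) = exhaustive_best(pool, d, w, vocab)
            nors.append(nor)
        assert nors[0] >= nors[1] >= nors[2]

    def test_empty_pool_is_an_error(self, toy_dataset):
        from fuzzyrules.rules import CandidatePool

        empty = CandidatePool(
            rules=[], criterion="product", min_confidence=0.6,
            min_support=0.05, q_requested=4,
        )
        with pytest.raises(ValueError, match="empty"):
            evolve(
                empty, toy_dataset, ObjectiveWeights(0.5, 0.3, 0.2),
                GAConfig(seed=0),
            )

    def test_trace_exports_expected_columns(self, random_pool, tmp_path):
        import pandas as pd

        pool, d = random_pool
        _, trace = evolve(
            pool, d, ObjectiveWeights(0.5, 0.3, 0.2),
            GAConfig(n_pop=6, max_generations=5, seed=1),
        )
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == [
            "generation", "fitness", "test_accuracy", "nor", "noa",
        ]
        assert len(df) == 5


class TestGAConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            GAConfig(n_pop=1)
        with pytest.raises(ValueError):
            GAConfig(p_c=1.5)
        with pytest.raises(ValueError):
            GAConfig(max_generations=0)
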