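import math

import numpy as np
import pytest

from ehrpred.corpus_io import PatientHistory, SequenceDataset
from ehrpred.ngram import (
    BOS,
    UNK,
    collective_predictability,
    cross_entropy,
    cross_validate,
    fit_ngram,
    joint_ngram_probabilities,
    make_folds,
    perplexity,
    sequence_log_loss,
    stability,
    weighted_percentile,
)
from ehrpred.synthetic import (
    MarkovSource,
    markov_entropy_rate,
    random_higher_order_source,
    sample_cohort,
)

from conftest import random_history


def seq_dataset(*code_lists):
    return SequenceDataset(
        [
            PatientHistory(f"p{i}", [(t, c) for t, c in enumerate(codes)])
            for i, codes in enumerate(code_lists)
        ]
    )


# ---------------------------------------------------------------------------
# independent oracle: direct counting + explicit smoothing arithmetic
# ---------------------------------------------------------------------------


def oracle_counts(code_lists, order):
    """Naive n-gram counting with BOS padding, written independently."""
    counts = {}
    for codes in code_lists:
        toks = [BOS] * (order - 1) + list(codes)
        for i in range(order - 1, len(toks)):
            ctx = tuple(toks[i - order + 1 : i])
            counts.setdefault(ctx, {})
            counts[ctx][toks[i]] = counts[ctx].get(toks[i], 0) + 1
    return counts


def oracle_additive_prob(code_lists, order, ctx, sym, vocab_size, delta):
    counts = oracle_counts(code_lists, order)
    table = counts.get(tuple(ctx), {})
    total = sum(table.values())
    return (table.get(sym, 0) + delta) / (total + delta * vocab_size)


def oracle_wb_prob(code_lists, ctx, sym, vocab):
    """Witten-Bell interpolation computed by explicit recursion on
    independently gathered counts."""
    order = len(ctx) + 1
    counts = oracle_counts(code_lists, order)
    table = counts.get(tuple(ctx), {})
    if order == 1:
        total = sum(table.values())
        t = len(table)
        return (table.get(sym, 0) + t / len(vocab)) / (total + t)
    lower = oracle_wb_prob(code_lists, ctx[1:], sym, vocab)
    if not table:
        return lower
    total = sum(table.values())
    t = len(table)
    return (table.get(sym, 0) + t * lower) / (total + t)


# ---------------------------------------------------------------------------


class TestFit:
    def test_unigram_frequencies(self):
        m = fit_ngram(seq_dataset(["a", "a", "b"]), 1, smoothing="additive", delta=1e-9)
        assert m.prob("a", []) == pytest.approx(2 / 3, abs=1e-6)
        assert m.prob("b", []) == pytest.approx(1 / 3, abs=1e-6)

    def test_deterministic_cycle_bigram(self):
        d = seq_dataset(["a", "b"] * 50)
        m = fit_ngram(d, 2, smoothing="additive", delta=1e-9)
        assert m.prob("b", ["a"]) == pytest.approx(1.0, abs=1e-6)

    def test_order_below_one_is_an_error(self, toy_dataset):
        with pytest.raises(ValueError):
            fit_ngram(toy_dataset, 0)

    @pytest.mark.parametrize("smoothing", ["witten_bell", "kneser_ney", "additive"])
    def test_conditional_distributions_sum_to_one(self, rng, smoothing):
        for trial in range(25):
            n_pat = int(rng.integers(2, 8))
            d = SequenceDataset(
                [random_history(rng, int(rng.integers(3, 15)), 4, f"p{i}") for i in range(n_pat)]
            )
            order = int(rng.integers(1, 4))
            m = fit_ngram(d, order, smoothing=smoothing)
            contexts = [d.histories[0].codes[: order - 1],
                        (BOS,) * (order - 1),
                        ("never-seen",) * (order - 1)]
            for ctx in contexts:
                total = sum(m.prob(s, ctx) for s in m.vocabulary)
                assert total == pytest.approx(1.0, abs=1e-9)


class TestLogLossAndCrossEntropy:
    def test_deterministic_cycle_near_zero_bits(self):
        d = seq_dataset(*[["a", "b"] * 30 for _ in range(5)])
        m = fit_ngram(d, 2)
        assert cross_entropy(m, d) < 0.05

    def test_uniform_unigram_gives_log_alphabet(self, rng):
        codes = [f"c{i}" for i in rng.integers(0, 16, size=20000)]
        d = seq_dataset(codes)
        m = fit_ngram(d, 1)
        assert cross_entropy(m, d) == pytest.approx(4.0, abs=0.05)

    def test_hand_computed_toy_additive(self):
        # train: single history a b a c a; bigram, delta=0.5, vocab={a,b,c,UNK}
        train = seq_dataset(["a", "b", "a", "c", "a"])
        m = fit_ngram(train, 2, smoothing="additive", delta=0.5)
        v = 4
        # bigram counts: (BOS,a) (a,b) (b,a) (a,c) (c,a); context "a" total 2
        # score "a b" : p(a|BOS) = (1+.5)/(1+.5*4), p(b|a) = (1+.5)/(2+.5*4)
        expected = -(math.log2(1.5 / 3.0) + math.log2(1.5 / 4.0))
        assert sequence_log_loss(m, ["a", "b"]) == pytest.approx(expected, abs=1e-12)

    def test_oov_symbols_score_as_unk_and_stay_finite(self):
        m = fit_ngram(seq_dataset(["a", "b", "a"]), 2)
        loss = sequence_log_loss(m, ["zzz", "a", "qqq"])
        assert np.isfinite(loss) and loss > 0

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_enumeration_oracle(self, rng, order):
        """Cross-entropy equals a direct enumeration of all conditional
        probabilities on a small alphabet (both smoothers)."""
        train = [list(f"s{c}" for c in rng.integers(0, 5, size=12)) for _ in range(4)]
        valid = [list(f"s{c}" for c in rng.integers(0, 5, size=8)) for _ in range(2)]
        d_train, d_valid = seq_dataset(*train), seq_dataset(*valid)
        vocab = {c for h in train for c in h} | {UNK}

        for smoothing in ("witten_bell", "additive"):
            m = fit_ngram(d_train, order, smoothing=smoothing, delta=0.5)
            total, n_events = 0.0, 0
            for codes in valid:
                toks = [BOS] * (order - 1) + [c if c in vocab else UNK for c in codes]
                for i in range(order - 1, len(toks)):
                    ctx, sym = toks[i - order + 1 : i], toks[i]
                    if smoothing == "additive":
                        p = oracle_additive_prob(train, order, ctx, sym, len(vocab), 0.5)
                    else:
                        p = oracle_wb_prob(train, list(ctx), sym, vocab)
                    total -= math.log2(p)
                    n_events += 1
            assert cross_entropy(m, d_valid) == pytest.approx(total / n_events, abs=1e-9)

    def test_cross_entropy_bounded_below_by_source_rate(self):
        src = MarkovSource(("a", "b", "c"), np.array([[0.7, 0.2, 0.1],
                                                     [0.1, 0.7, 0.2],
                                                     [0.2, 0.1, 0.7]]))
        rate = markov_entropy_rate(src)
        train = sample_cohort(src, 100, 200, seed=0)
        valid = sample_cohort(src, 20, 200, seed=1)
        m = fit_ngram(train, 2)
        assert cross_entropy(m, valid) >= rate - 0.05


class TestPerplexity:
    def test_log_consistency(self, rng):
        for _ in range(10):
            d = SequenceDataset(
                [random_history(rng, 20, 5, f"p{i}") for i in range(4)]
            )
            m = fit_ngram(d, 2)
            assert perplexity(m, d) == pytest.approx(2 ** cross_entropy(m, d))

    def test_three_bits_is_perplexity_eight(self):
        codes = [f"c{i}" for i in np.random.default_rng(0).integers(0, 8, size=50000)]
        m = fit_ngram(seq_dataset(codes), 1)
        assert perplexity(m, seq_dataset(codes)) == pytest.approx(8.0, rel=0.02)


class TestCrossValidate:
    def test_fold_partition_deterministic(self):
        f1 = make_folds(4, 2, seed=9)
        f2 = make_folds(4, 2, seed=9)
        assert all((a == b).all() for a, b in zip(f1, f2))
        assert sorted(np.concatenate(f1).tolist()) == [0, 1, 2, 3]
        assert all(len(f) == 2 for f in f1)

    def test_fewer_patients_than_folds_is_an_error(self, toy_dataset):
        with pytest.raises(ValueError):
            cross_validate(toy_dataset, orders=[1], k=10)

    def test_bigram_beats_unigram_on_first_order_source(self):
        src = MarkovSource(("a", "b", "c"), np.array([[0.8, 0.15, 0.05],
                                                     [0.05, 0.8, 0.15],
                                                     [0.15, 0.05, 0.8]]))
        d = sample_cohort(src, 60, 100, seed=3)
        res = cross_validate(d, orders=[1, 2], k=5, seed=0)
        assert res[2].mean_cross_entropy < res[1].mean_cross_entropy

    def test_structure_exhausted_at_source_order(self):
        """On an order-2 source the order 2->3 improvement dominates 3->4."""
        src = random_higher_order_source(4, order=2, seed=8, concentration=0.15)
        d = sample_cohort(src, 80, 120, seed=4)
        res = cross_validate(d, orders=[2, 3, 4], k=5, seed=0)
        gain_23 = res[2].mean_cross_entropy - res[3].mean_cross_entropy
        gain_34 = res[3].mean_cross_entropy - res[4].mean_cross_entropy
        assert gain_23 > gain_34


class TestStability:
    def test_identical_models_have_zero_change(self, toy_dataset):
        m = fit_ngram(toy_dataset, 2)
        pct95, changes, _ = stability([m, m])
        assert pct95 == 0.0
        assert np.all(changes == 0.0)

    def test_hand_checkable_bigram_toy(self):
        d1 = seq_dataset(["a", "b", "a", "b"])
        d2 = seq_dataset(["a", "b", "a", "a"])
        m1 = fit_ngram(d1, 2, smoothing="additive", delta=0.1)
        m2 = fit_ngram(d2, 2, smoothing="additive", delta=0.1)
        j1 = joint_ngram_probabilities(m1)
        j2 = joint_ngram_probabilities(m2)
        _, changes, weights = stability([m1, m2])
        gram = ("a", "b")
        pa, pb = j1[gram], j2[gram]
        expected = abs(pa - pb) / ((pa + pb) / 2) * 100
        assert any(abs(expected - c) < 1e-9 for c in changes)

    def test_converges_with_sample_size(self):
        src = MarkovSource(("a", "b"), np.array([[0.8, 0.2], [0.3, 0.7]]))
        spreads = []
        for n in (40, 400):
            d = sample_cohort(src, n, 50, seed=5)
            _, models = cross_validate(d, orders=[2], k=2, seed=0, return_models=True)
            pct95, _, _ = stability(models[2])
            spreads.append(pct95)
        assert spreads[1] < spreads[0]

    def test_mismatched_orders_raise(self, toy_dataset):
        with pytest.raises(ValueError):
            stability([fit_ngram(toy_dataset, 2), fit_ngram(toy_dataset, 3)])


def test_weighted_percentile_simple():
    v = np.array([1.0, 2.0, 3.0])
    w = np.array([1.0, 1.0, 98.0])
    assert weighted_percentile(v, w, 50) == 3.0
    assert weighted_percentile(v, w, 1) == 1.0


class TestCollectivePredictability:
    def test_zero_cross_entropy_is_full_predictability(self):
        from ehrpred.ngram import CrossValidationResult

        cv = CrossValidationResult(2, "full", 0, (0.0, 0.0), n_symbols=50)
        assert collective_predictability(cv)["pi_mean"] == 1.0

    def test_monotone_in_cross_entropy(self):
        from ehrpred.ngram import CrossValidationResult

        lo = CrossValidationResult(2, "full", 0, (1.0,), n_symbols=50)
        hi = CrossValidationResult(2, "full", 0, (3.0,), n_symbols=50)
        assert collective_predictability(lo)["pi_mean"] > collective_predictability(hi)["pi_mean"]
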