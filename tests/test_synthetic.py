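import numpy as np
import pytest

from ehrpred.codes import Level
from ehrpred.corpus_io import write_dataset
from ehrpred.ngram import cross_entropy, fit_ngram
from ehrpred.shuffle import shuffle_within_patients
from ehrpred.synthetic import (
    CohortConfig,
    HigherOrderMarkovSource,
    MarkovSource,
    generate_cohort,
    generate_markov,
    generate_text_corpus,
    markov_entropy_rate,
    random_higher_order_source,
    sample_cohort,
    zipf_masses,
    zipf_top_share,
)


class TestCohortConfig:
    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(mean_len=10, min_len=20)
        with pytest.raises(ValueError):
            CohortConfig(chronic_fraction=1.5)

    def test_alphabet_size(self):
        cfg = CohortConfig()
        assert cfg.n_codes == 10 * 4 * 5 * 6


class TestGenerateCohort:
    def test_deterministic_under_seed(self, tmp_path):
        cfg = CohortConfig(n_patients=100, seed=17)
        d1, h1 = generate_cohort(cfg)
        d2, h2 = generate_cohort(cfg)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_dataset(d1, p1)
        write_dataset(d2, p2)
        assert p1.read_text() == p2.read_text()
        assert dict(h1.entries) == dict(h2.entries)

    def test_length_floor_and_mean_calibration(self):
        d, _ = generate_cohort(CohortConfig(n_patients=5000, seed=1))
        lengths = np.array([ph.n_h for ph in d])
        assert lengths.min() >= 20
        assert abs(lengths.mean() - 31.16) / 31.16 < 0.10

    def test_chronic_share_matches_config(self):
        _, _, meta = generate_cohort(CohortConfig(n_patients=3000, seed=2), return_meta=True)
        assert meta["chronic_share"] == pytest.approx(0.2, abs=0.02)

    def test_codes_resolve_in_emitted_hierarchy(self):
        d, h = generate_cohort(CohortConfig(n_patients=50, seed=3))
        assert all(c in h for c in d.alphabet)
        d2 = d.project(h, Level.CAT_2)
        assert len(d2.alphabet) <= h.level_sizes[Level.CAT_2]


class TestZipfCalibration:
    def test_head_concentration_at_full_scale(self):
        """At the ~12.5k-code scale, the top ~100 ranks of the default
        Zipf(1.0) marginal absorb about half the probability mass."""
        share = zipf_top_share(12462, 1.0, 100)
        assert share == pytest.approx(0.5, abs=0.05)

    def test_masses_normalised_and_decreasing(self):
        p = zipf_masses(1000, 1.0)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(np.diff(p) <= 0)


class TestMarkovOracles:
    def test_symmetric_two_state_rate(self):
        src = MarkovSource(("0", "1"), np.array([[0.9, 0.1], [0.1, 0.9]]))
        # closed form: binary entropy of the flip probability
        assert markov_entropy_rate(src) == pytest.approx(0.469, abs=0.001)

    def test_deterministic_cycle_has_zero_rate(self):
        src = MarkovSource(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert markov_entropy_rate(src) == 0.0

    def test_uniform_iid_over_eight_symbols(self):
        p = np.full((8, 8), 1 / 8)
        src = MarkovSource(tuple("abcdefgh"), p)
        assert markov_entropy_rate(src) == pytest.approx(3.0)

    def test_reducible_chain_rejected(self):
        src = MarkovSource(("a", "b"), np.array([[1.0, 0.0], [0.5, 0.5]]))
        with pytest.raises(ValueError, match="irreducible"):
            markov_entropy_rate(src)

    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError):
            MarkovSource(("a", "b"), np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_absorbing_single_state_is_constant(self):
        src = MarkovSource(("x",), np.array([[1.0]]))
        ph = generate_markov(src, 20, seed=0)
        assert set(ph.codes) == {"x"}

    def test_sample_path_deterministic(self):
        src = MarkovSource(("a", "b"), np.array([[0.7, 0.3], [0.4, 0.6]]))
        assert generate_markov(src, 100, seed=5).codes == generate_markov(src, 100, seed=5).codes

    def test_empirical_transitions_converge(self):
        p = np.array([[0.7, 0.3], [0.4, 0.6]])
        src = MarkovSource(("a", "b"), p)
        codes = generate_markov(src, 100_000, seed=9).codes
        idx = np.array([0 if c == "a" else 1 for c in codes])
        for i in range(2):
            nxt = idx[1:][idx[:-1] == i]
            freq = np.bincount(nxt, minlength=2) / len(nxt)
            np.testing.assert_allclose(freq, p[i], atol=0.01)


class TestHigherOrderSource:
    def test_entropy_rate_within_bounds(self):
        src = random_higher_order_source(4, order=2, seed=1, concentration=0.2)
        rate = src.entropy_rate()
        assert 0.0 < rate < 2.0  # log2(4) upper bound

    def test_order2_rate_matches_long_run_log_loss(self):
        """Empirical per-symbol log-loss of the true conditionals on a long
        sample path approaches the analytic entropy rate."""
        src = random_higher_order_source(3, order=2, seed=2, concentration=0.3)
        rng = np.random.default_rng(0)
        seq = src.sample(50_000, rng)
        idx = {s: i for i, s in enumerate(src.states)}
        total = 0.0
        for i in range(2, len(seq)):
            ctx = (idx[seq[i - 2]], idx[seq[i - 1]])
            total -= np.log2(src.conditionals[ctx][idx[seq[i]]])
        assert total / (len(seq) - 2) == pytest.approx(src.entropy_rate(), abs=0.02)

    def test_sample_cohort_deterministic(self):
        src = random_higher_order_source(3, order=2, seed=3)
        d1 = sample_cohort(src, 5, 30, seed=4)
        d2 = sample_cohort(src, 5, 30, seed=4)
        assert all(a.codes == b.codes for a, b in zip(d1, d2))


class TestTextCorpus:
    def test_deterministic_under_seed(self):
        t1 = generate_text_corpus(20, seed=6)
        t2 = generate_text_corpus(20, seed=6)
        assert all(a.codes == b.codes for a, b in zip(t1, t2))

    def test_single_word_lexicon_is_fully_repetitive(self):
        t = generate_text_corpus(10, seed=7, lexicon_size=1)
        words = {"".join(ph.codes).split(" ")[0] for ph in t}
        assert len(words) == 1

    def test_word_structure_carries_bigram_information(self):
        """Character bigram cross-entropy is lower on original text than on
        within-sentence shuffled text (word spellings are rigid)."""
        t = generate_text_corpus(400, seed=8)
        m = fit_ngram(t, 2)
        shuffled = shuffle_within_patients(t, seed=9)
        assert cross_entropy(m, t) < cross_entropy(m, shuffled) - 1.0
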