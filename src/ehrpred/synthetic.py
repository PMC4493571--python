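"""Synthetic cohorts, Markov oracles, and synthetic text.

The study data this package is designed for — large private EHR cohorts
— cannot be redistributed, so every analysis stage is exercised on
generated data with known ground truth:

* ``generate_cohort`` emulates the printed summary statistics of a
  large claims-style cohort at reduced scale: a hierarchical code
  alphabet, history lengths with a hard floor of 20 and mean ~31,
  Zipf-like code marginals whose head concentrates half the mass, and a
  ~20%/80% chronic/acute mixture where chronic events follow a small
  per-patient Markov progression over codes sharing a category parent
  (this is what makes temporal order informative);
* ``MarkovSource`` / ``HigherOrderMarkovSource`` are estimator-validation
  oracles with closed-form entropy rates;
* ``generate_text_corpus`` builds character sequences from a fixed
  lexicon of words, the natural-language analogue used to contrast
  shuffling behaviour of text with that of disease sequences.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from itertools import product
from math import log2

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .codes import CodeHierarchy
from .corpus_io import PatientHistory, SequenceDataset

__all__ = [
    "CohortConfig",
    "generate_hierarchy",
    "generate_cohort",
    "zipf_masses",
    "zipf_top_share",
    "MarkovSource",
    "HigherOrderMarkovSource",
    "random_higher_order_source",
    "generate_markov",
    "sample_cohort",
    "markov_entropy_rate",
    "generate_text_corpus",
]


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic-cohort generator.

    Defaults emulate, at reduced scale, a cohort with histories of at
    least 20 and on average ~31 codes, a four-level code hierarchy, 20%
    chronic events, and a Zipf(1.0) acute marginal (at the full ~12.5k
    alphabet that exponent puts ~50% of the mass on the top ~100 codes).
    """

    n_patients: int = 2000
    min_len: int = 20
    mean_len: float = 31.16
    n_chapters: int = 10
    cat2_per_chapter: int = 4
    cat3_per_cat2: int = 5
    codes_per_cat3: int = 6
    chronic_fraction: float = 0.2
    chronic_persistence: float = 0.6  # P(next event chronic | current chronic)
    acute_personal: float = 0.25  # P(acute event drawn from the patient's own block)
    zipf_exponent: float = 1.0
    markov_order: int = 1  # order of the chronic progression chains
    nb_dispersion: float = 3.0  # negative-binomial r of the length excess
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.mean_len < self.min_len:
            raise ValueError("mean_len must be >= min_len")
        if not 0.0 <= self.chronic_fraction <= 1.0:
            raise ValueError("chronic_fraction must be a probability")
        if not 0.0 <= self.chronic_persistence < 1.0:
            raise ValueError("chronic_persistence must be in [0, 1)")
        if not 0.0 <= self.acute_personal <= 1.0:
            raise ValueError("acute_personal must be a probability")
        if self.markov_order not in (1, 2):
            raise ValueError("chronic progression supports markov_order 1 or 2")

    @property
    def n_codes(self) -> int:
        return (
            self.n_chapters * self.cat2_per_chapter * self.cat3_per_cat2 * self.codes_per_cat3
        )


def zipf_masses(n: int, exponent: float) -> np.ndarray:
    """Normalised Zipf probabilities ``p_i ~ (i+1)^-exponent`` over n ranks."""
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def zipf_top_share(n: int, exponent: float, k: int) -> float:
    """Fraction of total mass carried by the top-``k`` ranks of a Zipf law."""
    p = zipf_masses(n, exponent)
    return float(p[:k].sum())


def generate_hierarchy(cfg: CohortConfig) -> CodeHierarchy:
    """Balanced synthetic hierarchy with the configured branching shape."""
    entries: dict[str, tuple[str, str, str]] = {}
    idx = 0
    for ch in range(cfg.n_chapters):
        for c2 in range(cfg.cat2_per_chapter):
            for c3 in range(cfg.cat3_per_cat2):
                for _ in range(cfg.codes_per_cat3):
                    code = f"d{idx:05d}"
                    entries[code] = (
                        f"c3_{ch:02d}.{c2}.{c3}",
                        f"c2_{ch:02d}.{c2}",
                        f"ch_{ch:02d}",
                    )
                    idx += 1
    return CodeHierarchy(entries)


def _chronic_chain(n_states: int, order: int, rng: np.random.Generator) -> np.ndarray:
    """Sticky-cyclic progression kernel over one code block.

    Rows mix a one-step cycle (progression), self-transition
    (persistence) and a Dirichlet perturbation, giving each block its
    own characteristic low-order structure.
    """
    eye = np.eye(n_states)
    cycle = np.roll(eye, 1, axis=1)
    if order == 1:
        # mostly exchangeable within the block (progressions are alternate
        # serialisations of the same code set) with a mild directed cycle
        noise = rng.dirichlet(np.full(n_states, 2.0), size=n_states)
        p = 0.25 * cycle + 0.1 * eye + 0.65 * noise
        return p / p.sum(axis=1, keepdims=True)
    # order 2: condition on the previous two states
    noise = rng.dirichlet(np.full(n_states, 2.0), size=(n_states, n_states))
    p = 0.25 * cycle[None, :, :] + 0.1 * eye[None, :, :] + 0.65 * noise
    # the first axis (state two steps back) perturbs the mixture so the
    # conditional law genuinely depends on both lags
    tilt = rng.dirichlet(np.ones(n_states), size=n_states)  # per-oldest-state tilt
    p = 0.7 * p + 0.3 * tilt[:, None, :]
    return p / p.sum(axis=2, keepdims=True)


def generate_cohort(
    cfg: CohortConfig, return_meta: bool = False
) -> tuple[SequenceDataset, CodeHierarchy] | tuple[SequenceDataset, CodeHierarchy, dict]:
    """Generate a synthetic cohort and its matching hierarchy.

    Per patient: the history length is ``min_len`` plus a
    negative-binomial excess hitting ``mean_len``; each event is chronic
    with probability ``chronic_fraction`` — drawn by stepping the
    patient's assigned progression chain over one cat3 code block — and
    otherwise acute, an i.i.d. Zipf draw over the full alphabet.
    Timestamps are the event indices.
    """
    rng = np.random.default_rng(cfg.seed)
    hierarchy = generate_hierarchy(cfg)
    codes = np.array(sorted(hierarchy.entries), dtype=object)
    n_codes = len(codes)
    acute_p = zipf_masses(n_codes, cfg.zipf_exponent)
    # ranks are assigned by a seeded permutation so the Zipf head is not
    # correlated with hierarchy position
    rank_of_code = rng.permutation(n_codes)
    acute_probs = np.empty(n_codes)
    acute_probs[rank_of_code] = acute_p

    n_blocks = cfg.n_chapters * cfg.cat2_per_chapter * cfg.cat3_per_cat2
    block_size = cfg.codes_per_cat3
    chains = [
        _chronic_chain(block_size, cfg.markov_order, rng) for _ in range(n_blocks)
    ]

    excess_mean = cfg.mean_len - cfg.min_len
    r = cfg.nb_dispersion
    p_nb = r / (r + excess_mean) if excess_mean > 0 else 1.0

    histories: list[PatientHistory] = []
    n_chronic_events = 0
    patient_block: list[int] = []
    for pid in range(cfg.n_patients):
        if excess_mean > 0:
            n_h = cfg.min_len + int(rng.negative_binomial(r, p_nb))
        else:
            n_h = cfg.min_len
        block = int(rng.integers(n_blocks))
        patient_block.append(block)
        chain = chains[block]
        base = block * block_size
        # chronic events arrive in persistent episodes (flare-ups): a
        # two-state chain whose stationary law matches chronic_fraction
        f, q = cfg.chronic_fraction, cfg.chronic_persistence
        p_enter = f * (1.0 - q) / (1.0 - f) if f < 1.0 else 1.0
        if p_enter > 1.0:
            raise ValueError("chronic_persistence too low for this chronic_fraction")
        u = rng.random(n_h)
        is_chronic = np.empty(n_h, dtype=bool)
        cur = u[0] < f
        is_chronic[0] = cur
        for t in range(1, n_h):
            cur = u[t] < (q if cur else p_enter)
            is_chronic[t] = cur
        n_acute = int((~is_chronic).sum())
        acute_draws = rng.choice(n_codes, size=n_acute, p=acute_probs) if n_acute else np.empty(0, np.int64)
        # recurrent acute conditions cluster in the patient's dominant
        # disease category: redirect a fraction into their own block
        personal = rng.random(n_acute) < cfg.acute_personal
        if personal.any():
            acute_draws = np.array(acute_draws)
            acute_draws[personal] = base + rng.integers(0, block_size, size=int(personal.sum()))
        state = int(rng.integers(block_size))
        prev = int(rng.integers(block_size))  # second lag for order-2 chains
        events: list[tuple[object, str]] = []
        a_idx = 0
        for t in range(n_h):
            if is_chronic[t]:
                if cfg.markov_order == 1:
                    nxt = int(rng.choice(block_size, p=chain[state]))
                else:
                    nxt = int(rng.choice(block_size, p=chain[prev, state]))
                prev, state = state, nxt
                events.append((t, str(codes[base + state])))
            else:
                events.append((t, str(codes[acute_draws[a_idx]])))
                a_idx += 1
        n_chronic_events += int(is_chronic.sum())
        histories.append(PatientHistory(f"p{pid:06d}", events, presorted=True))
    dataset = SequenceDataset(histories)
    if return_meta:
        meta = {
            "chronic_share": n_chronic_events / dataset.n_events,
            "patient_block": np.asarray(patient_block),
            "block_size": block_size,
        }
        return dataset, hierarchy, meta
    return dataset, hierarchy


# ---------------------------------------------------------------------------
# Markov oracles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovSource:
    """First-order Markov chain with a closed-form entropy rate."""

    states: tuple[str, ...]
    transition: np.ndarray  # row-stochastic
    initial: np.ndarray | None = None  # defaults to the stationary law

    def __post_init__(self) -> None:
        p = np.asarray(self.transition, dtype=float)
        if p.shape != (len(self.states), len(self.states)):
            raise ValueError("transition matrix shape must match the state count")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition-matrix rows must sum to 1")
        if self.initial is not None and not np.isclose(np.sum(self.initial), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    def stationary(self) -> np.ndarray:
        p = np.asarray(self.transition, dtype=float)
        vals, vecs = np.linalg.eig(p.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        mu = np.real(vecs[:, i])
        mu = np.abs(mu)
        return mu / mu.sum()

    def sample(self, n: int, rng: np.random.Generator) -> list[str]:
        p = np.asarray(self.transition, dtype=float)
        init = self.initial if self.initial is not None else self.stationary()
        cum = np.cumsum(p, axis=1)
        out = np.empty(n, dtype=np.int64)
        s = int(np.searchsorted(np.cumsum(init), rng.random()))
        out[0] = s
        u = rng.random(n)
        for i in range(1, n):
            s = int(np.searchsorted(cum[s], u[i]))
            out[i] = s
        return [self.states[i] for i in out]


def markov_entropy_rate(src: MarkovSource) -> float:
    """Analytic entropy rate ``-sum_i mu_i sum_j P_ij log2 P_ij`` in bits.

    Requires an irreducible chain (single strongly connected component
    of the support graph).
    """
    p = np.asarray(src.transition, dtype=float)
    n_comp, _ = connected_components(csr_matrix(p > 0), connection="strong")
    if n_comp != 1:
        raise ValueError("transition matrix is not irreducible")
    mu = src.stationary()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return float(-(mu @ plogp.sum(axis=1)))


def generate_markov(src: MarkovSource, n_tokens: int, seed: int) -> PatientHistory:
    """Seeded sample path of the chain as a single patient history."""
    rng = np.random.default_rng(seed)
    codes = src.sample(n_tokens, rng)
    return PatientHistory("markov", [(i, c) for i, c in enumerate(codes)], presorted=True)


@dataclass(frozen=True)
class HigherOrderMarkovSource:
    """Order-``m`` Markov source defined by per-context conditionals.

    ``conditionals[ctx]`` is the distribution of the next symbol given
    the last ``m`` symbols (as a tuple of state indices).  The entropy
    rate is computed exactly from the stationary law of the equivalent
    first-order chain over contexts.
    """

    states: tuple[str, ...]
    order: int
    conditionals: dict = field(hash=False)

    def _context_chain(self) -> MarkovSource:
        k = len(self.states)
        ctxs = list(product(range(k), repeat=self.order))
        index = {c: i for i, c in enumerate(ctxs)}
        p = np.zeros((len(ctxs), len(ctxs)))
        for c in ctxs:
            probs = self.conditionals[c]
            for s in range(k):
                p[index[c], index[c[1:] + (s,)]] += probs[s]
        return MarkovSource(tuple(map(str, range(len(ctxs)))), p)

    def entropy_rate(self) -> float:
        k = len(self.states)
        chain = self._context_chain()
        mu = chain.stationary()
        ctxs = list(product(range(k), repeat=self.order))
        rate = 0.0
        for w, c in zip(mu, ctxs):
            probs = np.asarray(self.conditionals[c])
            nz = probs[probs > 0]
            rate += w * float(-(nz * np.log2(nz)).sum())
        return rate

    def sample(self, n: int, rng: np.random.Generator, burn_in: int = 200) -> list[str]:
        k = len(self.states)
        ctx = tuple(int(x) for x in rng.integers(0, k, size=self.order))
        out: list[int] = []
        for i in range(burn_in + n):
            s = int(rng.choice(k, p=self.conditionals[ctx]))
            ctx = ctx[1:] + (s,)
            if i >= burn_in:
                out.append(s)
        return [self.states[s] for s in out]


def random_higher_order_source(
    n_states: int, order: int, seed: int, concentration: float = 0.2
) -> HigherOrderMarkovSource:
    """Dirichlet-random conditionals: low concentration = strong structure."""
    rng = np.random.default_rng(seed)
    states = tuple(string.ascii_lowercase[i] for i in range(n_states))
    cond = {
        c: rng.dirichlet(np.full(n_states, concentration)) + 1e-12
        for c in product(range(n_states), repeat=order)
    }
    cond = {c: p / p.sum() for c, p in cond.items()}
    return HigherOrderMarkovSource(states, order, cond)


def sample_cohort(src, n_patients: int, length: int, seed: int) -> SequenceDataset:
    """A cohort of independent sample paths from a Markov oracle."""
    rng = np.random.default_rng(seed)
    histories = []
    for pid in range(n_patients):
        codes = src.sample(length, rng)
        histories.append(
            PatientHistory(f"m{pid:05d}", [(i, c) for i, c in enumerate(codes)], presorted=True)
        )
    return SequenceDataset(histories)


# ---------------------------------------------------------------------------
# synthetic text
# ---------------------------------------------------------------------------


def generate_text_corpus(
    n_sentences: int,
    alphabet_size: int = 26,
    seed: int = 0,
    lexicon_size: int = 50,
    mean_words: float = 8.0,
) -> SequenceDataset:
    """Character sequences assembled from a fixed lexicon of words.

    Each "sentence" (one history per sentence, symbols = characters
    including a space separator) concatenates Zipf-distributed draws
    from a fixed lexicon of multi-letter words.  Word-internal letter
    order is rigid — the property that makes natural-language text
    behave so differently from disease sequences under shuffling.
    """
    rng = np.random.default_rng(seed)
    letters = string.ascii_lowercase[:alphabet_size]
    lexicon = []
    seen = set()
    while len(lexicon) < lexicon_size:
        length = int(rng.integers(2, 8))
        word = "".join(letters[i] for i in rng.integers(0, alphabet_size, size=length))
        if word not in seen:
            seen.add(word)
            lexicon.append(word)
    word_p = zipf_masses(lexicon_size, 1.1)
    histories = []
    for sid in range(n_sentences):
        n_words = 3 + int(rng.poisson(max(mean_words - 3, 0)))
        ids = rng.choice(lexicon_size, size=n_words, p=word_p)
        text = " ".join(lexicon[i] for i in ids)
        histories.append(
            PatientHistory(f"s{sid:05d}", [(i, ch) for i, ch in enumerate(text)], presorted=True)
        )
    return SequenceDataset(histories)


def scaled_config(base: CohortConfig, n_patients: int) -> CohortConfig:
    """Convenience: same generator conditions at a different cohort size."""
    return replace(base, n_patients=n_patients)
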