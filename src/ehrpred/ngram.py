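"""Collective analysis: smoothed n-gram models over the shared alphabet.

All patients' sequences are treated as emissions of one information
source over a common code alphabet, which lets standard language-model
machinery apply: an order-``n`` model estimates the conditional
distribution of the next code given the previous ``n - 1``, with
smoothing so held-out sequences always have finite log-loss.  Model
quality is measured by cross-entropy (bits/symbol, approximately
unbiased) and perplexity on held-out folds of a k-fold cross-validation,
and model stability by the spread of joint n-gram probabilities across
folds.

Sequences are padded with ``n - 1`` beginning-of-sequence (BOS) tokens;
there is no end-of-sequence token (histories are truncations, not
completed sentences) and BOS positions never enter cross-entropy
denominators.  Held-out codes absent from the training vocabulary score
as the reserved UNK token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import PatientHistory, SequenceDataset

__all__ = [
    "BOS",
    "UNK",
    "NGramModel",
    "CrossValidationResult",
    "fit_ngram",
    "sequence_log_loss",
    "cross_entropy",
    "perplexity",
    "make_folds",
    "cross_validate",
    "joint_ngram_probabilities",
    "stability",
    "weighted_percentile",
    "collective_predictability",
]

BOS = "<s>"
UNK = "<unk>"

_SMOOTHERS = ("witten_bell", "kneser_ney", "additive")


@dataclass
class NGramModel:
    """A smoothed order-``n`` conditional model over a code alphabet.

    ``counts[m]`` maps a context tuple of length ``m - 1`` to a dict of
    next-symbol counts, for every order ``m = 1..n`` (the lower orders
    back the smoothing).  ``vocabulary`` holds the training codes plus
    UNK; BOS is a context-only token and is never predicted.
    """

    order: int
    smoothing: str = "witten_bell"
    delta: float = 0.5  # additive-smoothing pseudo-count
    discount: float = 0.75  # Kneser-Ney absolute discount
    vocabulary: frozenset[str] = field(default_factory=frozenset)
    counts: list[dict] = field(default_factory=list)
    _totals: list[dict] = field(default_factory=list, repr=False)
    _cont: dict = field(default_factory=dict, repr=False)  # KN continuation counts
    _cont_total: int = field(default=0, repr=False)

    @property
    def n_symbols(self) -> int:
        """Alphabet size excluding the reserved BOS/UNK tokens."""
        return len(self.vocabulary - {UNK})

    # -- probability ---------------------------------------------------

    def prob(self, symbol: str, context: Sequence[str]) -> float:
        """``p(symbol | context)``; out-of-vocabulary symbols score as UNK."""
        if symbol not in self.vocabulary:
            symbol = UNK
        ctx = tuple(context)[-(self.order - 1):] if self.order > 1 else ()
        ctx = tuple(c if (c == BOS or c in self.vocabulary) else UNK for c in ctx)
        if len(ctx) < self.order - 1:
            ctx = (BOS,) * (self.order - 1 - len(ctx)) + ctx
        return self._dispatch(symbol, ctx)

    def cond_prob(self, symbol: str, context: Sequence[str]) -> float:
        """Conditional probability with a context *shorter* than order-1
        treated as marginalised (no BOS padding); used for joint
        probabilities of n-grams at arbitrary sequence positions."""
        if symbol not in self.vocabulary:
            symbol = UNK
        ctx = tuple(c if (c == BOS or c in self.vocabulary) else UNK for c in context)
        if len(ctx) > self.order - 1:
            ctx = ctx[-(self.order - 1):]
        return self._dispatch(symbol, ctx)

    def _dispatch(self, symbol: str, ctx: tuple) -> float:
        if self.smoothing == "witten_bell":
            return self._p_wb(symbol, ctx)
        if self.smoothing == "kneser_ney":
            return self._p_kn(symbol, ctx, top=True)
        return self._p_add(symbol, ctx)

    def logprob(self, symbol: str, context: Sequence[str]) -> float:
        return log2(self.prob(symbol, context))

    def _p_wb(self, sym: str, ctx: tuple) -> float:
        """Witten-Bell interpolation down to a uniform base distribution."""
        v = len(self.vocabulary)
        if not ctx:
            table = self.counts[0][()]
            total = self._totals[0][()]
            t = len(table)
            return (table.get(sym, 0) + t / v) / (total + t)
        m = len(ctx)  # order index m+1, counts[m]
        table = self.counts[m].get(ctx)
        lower = self._p_wb(sym, ctx[1:])
        if not table:
            return lower
        total = self._totals[m][ctx]
        t = len(table)
        return (table.get(sym, 0) + t * lower) / (total + t)

    def _p_add(self, sym: str, ctx: tuple) -> float:
        """Additive (Lidstone) smoothing at the top order only."""
        v = len(self.vocabulary)
        m = len(ctx)
        table = self.counts[m].get(ctx, {})
        total = self._totals[m].get(ctx, 0)
        return (table.get(sym, 0) + self.delta) / (total + self.delta * v)

    def _p_kn(self, sym: str, ctx: tuple, top: bool) -> float:
        """Interpolated Kneser-Ney with a fixed absolute discount.

        Lower orders use continuation counts; the base distribution is
        the add-one-smoothed continuation unigram so UNK keeps strictly
        positive mass.
        """
        d = self.discount
        if not ctx:
            v = len(self.vocabulary)
            return (self._cont.get(sym, 0) + 1) / (self._cont_total + v)
        m = len(ctx)
        table = self.counts[m].get(ctx)
        lower = self._p_kn(sym, ctx[1:], top=False)
        if not table:
            return lower
        total = self._totals[m][ctx]
        t = len(table)
        c = table.get(sym, 0)
        return max(c - d, 0.0) / total + d * t / total * lower

    # -- diagnostics ---------------------------------------------------

    def context_distribution(self, context: Sequence[str]) -> dict[str, float]:
        """Full conditional distribution over the vocabulary (sums to 1)."""
        return {s: self.prob(s, context) for s in self.vocabulary}


def _padded(codes: Sequence[str], order: int) -> tuple:
    return (BOS,) * (order - 1) + tuple(codes)


def fit_ngram(
    train: SequenceDataset | Iterable[PatientHistory],
    order: int,
    smoothing: str = "witten_bell",
    delta: float = 0.5,
    discount: float = 0.75,
) -> NGramModel:
    """Accumulate n-gram counts over a training dataset and return the model.

    Counts are kept for every order ``1..order`` so interpolation-style
    smoothers can back off; each history contributes one padded token
    stream and BOS is never a predicted symbol.
    """
    if order < 1:
        raise ValueError("n-gram order must be >= 1")
    if smoothing not in _SMOOTHERS:
        raise ValueError(f"unknown smoothing {smoothing!r}; choose from {_SMOOTHERS}")
    histories = train.histories if isinstance(train, SequenceDataset) else list(train)
    if not histories:
        raise ValueError("training dataset is empty")

    counts: list[dict] = [dict() for _ in range(order)]
    totals: list[dict] = [dict() for _ in range(order)]
    vocab: set[str] = set()
    for ph in histories:
        toks = _padded(ph.codes, order)
        vocab.update(ph.codes)
        for i in range(order - 1, len(toks)):
            sym = toks[i]
            for m in range(order):  # context length m
                ctx = toks[i - m : i]
                table = counts[m].setdefault(ctx, {})
                table[sym] = table.get(sym, 0) + 1
                totals[m][ctx] = totals[m].get(ctx, 0) + 1

    model = NGramModel(
        order=order,
        smoothing=smoothing,
        delta=delta,
        discount=discount,
        vocabulary=frozenset(vocab | {UNK}),
        counts=counts,
        _totals=totals,
    )
    if smoothing == "kneser_ney" and order > 1:
        # continuation counts: number of distinct single-symbol contexts
        # each symbol follows
        cont: dict[str, int] = {}
        for ctx in counts[1]:
            for sym in counts[1][ctx]:
                cont[sym] = cont.get(sym, 0) + 1
        model._cont = cont
        model._cont_total = sum(cont.values())
    return model


def sequence_log_loss(m: NGramModel, ph: PatientHistory | Sequence[str]) -> float:
    """Total ``-log2 p`` of one history under the model, in bits."""
    codes = ph.codes if isinstance(ph, PatientHistory) else tuple(ph)
    toks = _padded(codes, m.order)
    total = 0.0
    for i in range(m.order - 1, len(toks)):
        total -= m.logprob(toks[i], toks[i - m.order + 1 : i])
    return total


def cross_entropy(m: NGramModel, valid: SequenceDataset | Iterable[PatientHistory]) -> float:
    """Pooled held-out cross-entropy in bits per symbol.

    Total log-loss over all validation events divided by the event
    count; BOS padding never enters the denominator.
    """
    histories = valid.histories if isinstance(valid, SequenceDataset) else list(valid)
    if not histories:
        raise ValueError("validation dataset is empty")
    total_bits = sum(sequence_log_loss(m, ph) for ph in histories)
    total_events = sum(len(ph.codes) if isinstance(ph, PatientHistory) else len(ph) for ph in histories)
    return total_bits / total_events


def perplexity(m: NGramModel, valid) -> float:
    """``2 ** cross_entropy``: effective branching factor of the model."""
    return 2.0 ** cross_entropy(m, valid)


@dataclass(frozen=True)
class CrossValidationResult:
    """Per-fold cross-entropy/perplexity for one model order."""

    order: int
    level: str
    seed: int
    fold_cross_entropy: tuple[float, ...]
    n_symbols: int  # training-vocabulary size (BOS/UNK excluded)

    @property
    def fold_perplexity(self) -> tuple[float, ...]:
        return tuple(2.0 ** h for h in self.fold_cross_entropy)

    @property
    def mean_cross_entropy(self) -> float:
        return float(np.mean(self.fold_cross_entropy))


def make_folds(n_patients: int, k: int, seed: int) -> list[np.ndarray]:
    """Partition patient indices into ``k`` folds by a seeded permutation."""
    if n_patients < k:
        raise ValueError(f"need at least {k} patients for {k}-fold cross-validation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_patients)
    return [np.sort(part) for part in np.array_split(perm, k)]


def cross_validate(
    d: SequenceDataset,
    orders: Sequence[int],
    k: int = 10,
    seed: int = 0,
    smoothing: str = "witten_bell",
    return_models: bool = False,
):
    """k-fold cross-validated cross-entropy for each model order.

    Patients are split into ``k`` folds by a seeded permutation; per
    fold, the model trains on the other ``k - 1`` folds (90% at the
    default ``k = 10``) and is scored on the held-out fold.

    Returns a dict ``order -> CrossValidationResult``; with
    ``return_models=True`` also a dict ``order -> list[NGramModel]``.
    """
    folds = make_folds(len(d.histories), k, seed)
    results: dict[int, CrossValidationResult] = {}
    models: dict[int, list[NGramModel]] = {}
    for order in orders:
        ces: list[float] = []
        fold_models: list[NGramModel] = []
        n_sym = 0
        for held in folds:
            held_set = set(held.tolist())
            train = [ph for i, ph in enumerate(d.histories) if i not in held_set]
            valid = [d.histories[i] for i in held]
            m = fit_ngram(train, order, smoothing=smoothing)
            ces.append(cross_entropy(m, valid))
            n_sym = max(n_sym, m.n_symbols)
            if return_models:
                fold_models.append(m)
        results[order] = CrossValidationResult(
            order=order,
            level=d.level.value,
            seed=seed,
            fold_cross_entropy=tuple(ces),
            n_symbols=n_sym,
        )
        models[order] = fold_models
    if return_models:
        return results, models
    return results


def joint_ngram_probabilities(m: NGramModel) -> dict[tuple, float]:
    """Smoothed joint probability of every observed top-order n-gram.

    Only n-grams of real codes are included (BOS-padded contexts are
    boundary artefacts).  The joint factorises through the model's own
    smoothed conditionals, ``p(w1) p(w2|w1) ... p(wn|w1..wn-1)``, so
    every value is strictly positive and comparable across folds.
    """
    out: dict[tuple, float] = {}
    top = m.counts[m.order - 1]
    for ctx, table in top.items():
        if BOS in ctx:
            continue
        for sym in table:
            gram = ctx + (sym,)
            p = 1.0
            for j, w in enumerate(gram):
                p *= m.cond_prob(w, gram[:j])
            out[gram] = p
    return out


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Percentile of ``values`` under ``weights`` (q in [0, 100])."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cum, q / 100.0, side="left").clip(max=len(v) - 1)])


def stability(models: Sequence[NGramModel], q: float = 95.0):
    """Frequency-weighted spread of joint n-gram probabilities across folds.

    For every n-gram observed in the first (reference) fold, the percent
    change of its joint probability against each other fold is
    ``|p_a - p_b| / ((p_a + p_b)/2) * 100``; changes are weighted by the
    n-gram's occurrence count in the reference fold, so the headline
    number reflects the grams a patient actually encounters.  Returns
    ``(percentile_value, changes, weights)``.
    """
    if len(models) < 2:
        raise ValueError("stability needs at least two fold models")
    order = models[0].order
    if any(m.order != order for m in models):
        raise ValueError("all fold models must have the same order")
    ref = models[0]
    ref_joint = joint_ngram_probabilities(ref)
    ref_counts = {
        ctx + (sym,): c
        for ctx, table in ref.counts[order - 1].items()
        if BOS not in ctx
        for sym, c in table.items()
    }
    changes: list[float] = []
    weights: list[float] = []
    for other in models[1:]:
        other_joint = joint_ngram_probabilities(other)
        for gram, pa in ref_joint.items():
            pb = other_joint.get(gram)
            if pb is None:
                # score against the other model's smoothed estimate
                p = 1.0
                for j, w in enumerate(gram):
                    p *= other.cond_prob(w, gram[:j])
                pb = p
            changes.append(abs(pa - pb) / ((pa + pb) / 2.0) * 100.0)
            weights.append(ref_counts[gram])
    changes_a = np.asarray(changes)
    weights_a = np.asarray(weights, dtype=float)
    return weighted_percentile(changes_a, weights_a, q), changes_a, weights_a


def collective_predictability(
    cv: CrossValidationResult, n_symbols: int | None = None
) -> dict[str, float]:
    """Fano bounds from a cross-validation result's fold cross-entropies.

    The alphabet size defaults to the training-vocabulary size recorded
    in the result.  Returns mean and fold min/max of Pi.
    """
    from .predictability import fano_upper_bound

    n = n_symbols if n_symbols is not None else cv.n_symbols
    smax = log2(n) if n > 1 else 0.0
    pis = [fano_upper_bound(min(h, smax), n).pi_max for h in cv.fold_cross_entropy]
    return {
        "order": cv.order,
        "pi_mean": float(np.mean(pis)),
        "pi_min": float(np.min(pis)),
        "pi_max": float(np.max(pis)),
    }
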