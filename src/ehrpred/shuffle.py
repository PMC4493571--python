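"""Null models: within-patient permutation (D') and global swaps (D'').

Two seeded randomisations probe where the predictive information in a
cohort lives.  The first permutes the order of events inside each
patient, destroying temporal order while keeping every patient's code
multiset; the second repeatedly swaps randomly chosen codes between
randomly chosen patients, eventually destroying the association between
a patient and their set of codes while conserving the global code
multiset exactly.  Evaluating a model trained on the *original* data
against matched held-out slices of each variant separates the value of
within-patient order from the value of the patient's "bag of codes".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import PatientHistory, SequenceDataset
from .ngram import cross_entropy, fit_ngram, make_folds
from .predictability import fano_upper_bound

__all__ = [
    "ShufflePlan",
    "shuffle_within_patients",
    "shuffle_global_swaps",
    "shuffle_experiment",
]


@dataclass(frozen=True)
class ShufflePlan:
    """Seeded specification of a null construction."""

    mode: str  # "within_patient" | "global_swap"
    seed: int
    iterations: int | None = None  # swap count; None = 10x total tokens

    def apply(self, d: SequenceDataset) -> SequenceDataset:
        if self.mode == "within_patient":
            return shuffle_within_patients(d, self.seed)
        if self.mode == "global_swap":
            its = self.iterations if self.iterations is not None else 10 * d.n_events
            return shuffle_global_swaps(d, self.seed, its)
        raise ValueError(f"unknown shuffle mode {self.mode!r}")


def shuffle_within_patients(d: SequenceDataset, seed: int) -> SequenceDataset:
    """Permute each patient's codes uniformly at random (D').

    Timestamps stay in their original slots, so lengths and per-patient
    code multisets are preserved; only the order of codes changes.
    """
    rng = np.random.default_rng(seed)
    histories = []
    for ph in d.histories:
        codes = np.asarray(ph.codes, dtype=object)
        histories.append(ph.with_codes(codes[rng.permutation(len(codes))]))
    return SequenceDataset(histories, level=d.level)


def shuffle_global_swaps(d: SequenceDataset, seed: int, iterations: int) -> SequenceDataset:
    """Randomise the cohort by repeated cross-patient code swaps (D'').

    Each iteration picks two random patients and swaps one randomly
    chosen code between them.  Per-patient lengths and the global code
    multiset are conserved exactly; after enough iterations (default in
    :class:`ShufflePlan`: 10x the token count) each patient's codes are
    close to draws from the global marginal.
    """
    if len(d.histories) < 2:
        raise ValueError("global swaps need at least two patients")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    rng = np.random.default_rng(seed)
    codes = [list(ph.codes) for ph in d.histories]
    lengths = np.array([len(c) for c in codes])
    n_pat = len(codes)
    # draw in blocks to keep the Python loop lean
    pat_i = rng.integers(0, n_pat, size=iterations)
    pat_j = rng.integers(0, n_pat, size=iterations)
    u_i = rng.random(iterations)
    u_j = rng.random(iterations)
    pos_i = (u_i * lengths[pat_i]).astype(np.int64)
    pos_j = (u_j * lengths[pat_j]).astype(np.int64)
    for i, j, ki, kj in zip(pat_i, pat_j, pos_i, pos_j):
        ci, cj = codes[i], codes[j]
        ci[ki], cj[kj] = cj[kj], ci[ki]
    histories = [ph.with_codes(c) for ph, c in zip(d.histories, codes)]
    return SequenceDataset(histories, level=d.level)


def shuffle_experiment(
    d: SequenceDataset,
    order: int = 2,
    k: int = 10,
    seed: int = 0,
    smoothing: str = "witten_bell",
    iterations: int | None = None,
) -> pd.DataFrame:
    """Evaluate one model against matched original/shuffled hold-outs.

    Per cross-validation fold, a model of the given order is trained on
    the *original* training patients and scored on the held-out fold
    three ways: the original sequences (V), the within-patient-shuffled
    ones (V'), and the globally swapped ones (V'').  The same patient
    ids are held out in every variant.  Returns a tidy frame with one
    row per (fold, variant): cross-entropy and the Fano bound Pi at the
    training-vocabulary alphabet size.
    """
    d_prime = shuffle_within_patients(d, seed + 1)
    its = iterations if iterations is not None else 10 * d.n_events
    d_dprime = shuffle_global_swaps(d, seed + 2, its)

    folds = make_folds(len(d.histories), k, seed)
    rows = []
    for fold_idx, held in enumerate(folds):
        held_set = set(held.tolist())
        train = [ph for i, ph in enumerate(d.histories) if i not in held_set]
        m = fit_ngram(train, order, smoothing=smoothing)
        n_sym = m.n_symbols
        smax = np.log2(n_sym) if n_sym > 1 else 0.0
        for name, variant in (("V", d), ("V'", d_prime), ("V''", d_dprime)):
            valid = [variant.histories[i] for i in held]
            ce = cross_entropy(m, valid)
            pi = fano_upper_bound(min(ce, smax), n_sym).pi_max
            rows.append(
                {
                    "fold": fold_idx,
                    "variant": name,
                    "order": order,
                    "cross_entropy": ce,
                    "pi": pi,
                    "n_symbols": n_sym,
                }
            )
    return pd.DataFrame(rows)
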