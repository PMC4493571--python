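"""Per-patient entropy statistics: S^rnd, S^unc and S^cor.

Three estimators of the information content of one diagnosis sequence,
each assuming progressively more knowledge of its structure:

* **random entropy** ``S_rnd = log2(N_h)`` — uniform guessing over the
  ``N_h`` distinct codes appearing in the history;
* **uncorrelated entropy** ``S_unc = -sum_c p_c log2 p_c`` — Shannon
  entropy of the empirical code frequencies (order-free);
* **correlated entropy** ``S_cor = n log2(n) / sum_k Gamma_k`` — the
  Lempel–Ziv match-length entropy-rate estimator, where ``Gamma_k`` is
  the length of the shortest subsequence starting at position ``k`` that
  does not appear earlier in the history.  This is the only statistic
  sensitive to temporal order.

All values are in bits per symbol (base-2 throughout).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np

from .corpus_io import PatientHistory, SequenceDataset

__all__ = [
    "EntropyTriple",
    "MatchLengthProfile",
    "random_entropy",
    "uncorrelated_entropy",
    "match_lengths",
    "correlated_entropy",
    "entropy_profile",
]


@dataclass(frozen=True)
class EntropyTriple:
    """The three entropy statistics of one history, plus its size counts."""

    patient_id: str
    n_h: int
    n_distinct: int
    s_rnd: float
    s_unc: float
    s_cor: float


@dataclass(frozen=True)
class MatchLengthProfile:
    """Gamma_k values, k = 1..n (1-based positions).

    Gamma_1 = 1 always; 1 <= Gamma_k <= n - k + 2, the upper value occurring
    when the entire remaining suffix reappears earlier.
    """

    gammas: tuple[int, ...]


def _codes(ph) -> tuple[str, ...]:
    if isinstance(ph, PatientHistory):
        return ph.codes
    return tuple(ph)


def random_entropy(ph) -> float:
    """log2 of the number of distinct codes in the history."""
    codes = _codes(ph)
    if not codes:
        raise ValueError("empty history has no defined entropy")
    return log2(len(set(codes)))


def uncorrelated_entropy(ph) -> float:
    """Shannon entropy of the empirical code frequencies, in bits."""
    codes = _codes(ph)
    if not codes:
        raise ValueError("empty history has no defined entropy")
    _, counts = np.unique(np.asarray(codes, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def match_lengths(ph) -> MatchLengthProfile:
    """Shortest-previously-unseen-substring lengths Gamma_k.

    For 1-based position k, Gamma_k = 1 + L_k where L_k is the length of
    the longest substring starting at k that also starts somewhere in
    positions 1..k-1 (the match may run past position k-1, the standard
    overlapping-match convention).  Gamma_1 = 1; when the suffix at k
    never reappears Gamma_k = 1; when the entire remaining suffix
    matches, Gamma_k = n - k + 2.

    The search is vectorised per position: candidate start positions are
    the earlier occurrences of the symbol at k, pruned one extension at
    a time, so typical cost is near-linear for sequences with finite
    entropy rate.
    """
    codes = _codes(ph)
    n = len(codes)
    if n == 0:
        raise ValueError("empty history has no match-length profile")
    # integer-encode for fast vectorised comparisons
    _, arr = np.unique(np.asarray(codes, dtype=object), return_inverse=True)
    arr = arr.astype(np.int64)
    # occurrence positions per symbol, and rank of each position within them
    occ: dict[int, list[int]] = {}
    occ_arrays: dict[int, np.ndarray] = {}
    rank = np.empty(n, dtype=np.int64)
    for i, s in enumerate(arr):
        lst = occ.setdefault(int(s), [])
        rank[i] = len(lst)
        lst.append(i)
    for s, lst in occ.items():
        occ_arrays[s] = np.asarray(lst, dtype=np.int64)

    gammas = np.ones(n, dtype=np.int64)
    for k in range(1, n):
        js = occ_arrays[int(arr[k])][: rank[k]]  # earlier starts of this symbol
        if js.size == 0:
            continue
        ell = 1
        while k + ell < n:
            js = js[arr[js + ell] == arr[k + ell]]
            if js.size == 0:
                break
            ell += 1
        gammas[k] = ell + 1
    return MatchLengthProfile(tuple(int(g) for g in gammas))


def correlated_entropy(ph) -> float:
    """Match-length entropy-rate estimate ``n log2(n) / sum Gamma_k`` in bits.

    Undefined for histories of length 1 (raises ``ValueError``).
    """
    codes = _codes(ph)
    n = len(codes)
    if n < 2:
        raise ValueError("correlated entropy requires a history of length >= 2")
    total = sum(match_lengths(codes).gammas)
    return n * log2(n) / total


def entropy_profile(d: SequenceDataset) -> list[EntropyTriple]:
    """Compute the entropy triple for every patient, preserving order."""
    out: list[EntropyTriple] = []
    for ph in d.histories:
        try:
            codes = ph.codes
            out.append(
                EntropyTriple(
                    patient_id=ph.patient_id,
                    n_h=ph.n_h,
                    n_distinct=len(set(codes)),
                    s_rnd=random_entropy(codes),
                    s_unc=uncorrelated_entropy(codes),
                    s_cor=correlated_entropy(codes),
                )
            )
        except ValueError as exc:
            raise ValueError(f"patient {ph.patient_id}: {exc}") from exc
    return out
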