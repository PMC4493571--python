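"""Fano-type predictability bounds from entropy estimates.

Given an entropy rate ``S`` (bits/symbol) and an alphabet of ``N``
symbols, the maximal probability ``Pi`` of correctly guessing the next
symbol consistent with that entropy solves

    S = H(Pi) + (1 - Pi) * log2(N - 1),
    H(Pi) = -Pi*log2(Pi) - (1 - Pi)*log2(1 - Pi).

The right-hand side is the entropy of a source that concentrates mass
``Pi`` on one symbol and spreads the rest uniformly; it peaks at
``Pi = 1/N`` and decreases on ``[1/N, 1]``.  The upper predictability
bound is the root on that decreasing branch, so ``Pi(0, N) = 1`` and
``Pi(log2 N, N) = 1/N`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

from scipy.optimize import brentq

from .entropy import EntropyTriple

__all__ = [
    "PredictabilityResult",
    "fano_upper_bound",
    "naive_success_probability",
    "random_baseline",
    "predictability_profile",
]

# relative headroom for estimator noise pushing S slightly above log2(N)
_EPS_REL = 1e-9
_XTOL = 1e-12


@dataclass(frozen=True)
class PredictabilityResult:
    pi_max: float
    s: float
    n_symbols: int
    branch: str = "upper"  # the decreasing branch Pi in [1/N, 1]


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * log2(p) - (1.0 - p) * log2(1.0 - p)


def fano_upper_bound(s: float, n: int) -> PredictabilityResult:
    """Solve the Fano equality for the maximal predictability Pi.

    Parameters
    ----------
    s : entropy in bits, ``0 <= s <= log2(n)`` (tiny overshoot from
        estimator noise is clamped to ``Pi = 1/n``).
    n : alphabet size, ``n >= 1``.

    Raises
    ------
    ValueError
        For negative entropy, ``n < 1``, or ``s`` exceeding ``log2 n``
        beyond the noise tolerance (inconsistent inputs).
    """
    if n < 1:
        raise ValueError("alphabet size must be >= 1")
    if s < 0:
        raise ValueError("entropy must be non-negative")
    if n == 1:
        return PredictabilityResult(1.0, s, n)
    smax = log2(n)
    if s > smax:
        if s <= smax * (1.0 + _EPS_REL) + _EPS_REL:
            return PredictabilityResult(1.0 / n, s, n)
        raise ValueError(f"entropy {s} bits exceeds log2({n}) = {smax}: inconsistent inputs")
    if s == 0.0:
        return PredictabilityResult(1.0, s, n)

    tail = log2(n - 1)

    def f(pi: float) -> float:
        return _binary_entropy(pi) + (1.0 - pi) * tail - s

    lo, hi = 1.0 / n, 1.0 - 1e-16
    if f(lo) <= 0.0:  # s at the top of the decreasing branch (within rounding)
        return PredictabilityResult(1.0 / n, s, n)
    if f(hi) >= 0.0:  # s below the entropy floor of the one-spike family
        return PredictabilityResult(1.0, s, n)
    pi = brentq(f, lo, hi, xtol=_XTOL)
    return PredictabilityResult(float(pi), s, n)


def naive_success_probability(s: float) -> float:
    """``2**-s``: success probability under the effective-alphabet reading.

    An entropy of ``s`` bits corresponds to an effective alphabet of
    ``2**s`` equally likely codes; this is distinct from (and below) the
    Fano upper bound.
    """
    if s < 0:
        raise ValueError("entropy must be non-negative")
    return 2.0 ** (-s)


def random_baseline(n: int) -> float:
    """``1/n``: chance of guessing uniformly among ``n`` symbols."""
    if n < 1:
        raise ValueError("alphabet size must be >= 1")
    return 1.0 / n


def predictability_profile(
    triples: list[EntropyTriple],
) -> list[tuple[float, float, float]]:
    """Per-patient ``(Pi_rnd, Pi_unc, Pi_cor)`` from the entropy triples.

    Each bound uses the patient's own distinct-code count as the
    alphabet size; ``Pi_rnd = 1/N_h`` by construction.
    """
    out = []
    for t in triples:
        try:
            pi_rnd = fano_upper_bound(t.s_rnd, t.n_distinct).pi_max
            pi_unc = fano_upper_bound(t.s_unc, t.n_distinct).pi_max
            pi_cor = fano_upper_bound(min(t.s_cor, t.s_rnd), t.n_distinct).pi_max
        except ValueError as exc:
            raise ValueError(f"patient {t.patient_id}: {exc}") from exc
        out.append((pi_rnd, pi_unc, pi_cor))
    return out
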