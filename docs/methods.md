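# Methods

This note documents the models, estimators, numerical choices and known
limitations of `ehrpred`, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

A patient history is an ordered list of `(time, code)` events. Timestamps
are used *only* to fix the order of events; absolute time is never
modelled, which insulates the analysis from non-stationarity tied to
calendar events (care-practice changes, coding-system updates).
Simultaneous events are serialised by a stable sort on the code string — a
deterministic convention chosen because within-visit order is unrecorded,
and the shuffle experiments themselves show within-patient order to be
weakly informative. Repeated identical codes are kept as recorded; no
within-visit deduplication is performed, since the recurrence of a code is
itself signal for the frequency-based statistics.

The code hierarchy is supplied as data (TSV: `code cat3 cat2 chapter`),
never hard-coded: category identifiers are opaque strings, so ICD-9
dialects (V/E codes) and synthetic hierarchies are handled identically.
Level sizes are data-dependent properties of the supplied table, not
constants of the package.

## Per-patient entropy statistics

For a history of length `n_h` with `N_h` distinct codes:

- `S_rnd = log2 N_h`;
- `S_unc = −Σ p_c log2 p_c` over the empirical code frequencies;
- `S_cor = n_h log2(n_h) / Σ_k Γ_k`, the Lempel–Ziv match-length
  entropy-rate estimator. `Γ_k` is `1 + L_k` where `L_k` is the length of
  the longest substring starting at position `k` that also starts at some
  earlier position; matches may overlap into positions `≥ k` (the standard
  convention for this estimator). `Γ_1 = 1`; if the whole remaining suffix
  recurs, `Γ_k` attains its cap `n_h − k + 2` (1-based), which keeps
  `Σ Γ` finite.

The estimator is consistent for stationary ergodic sources and converges
quickly, but individual disease histories are short (tens of events) and
not stationary; per-patient values should be read as descriptive
statistics whose *distributional* comparisons (one-sided KS) carry the
inference. The implementation prunes candidate match starts one extension
at a time with vectorised comparisons — near-linear cost on
finite-entropy sequences — and is verified against an `O(n^3)` brute-force
substring search on hundreds of random sequences.

For repeat-free histories `Γ_k ≡ 1` and `S_cor = S_rnd` exactly; on
match-rich sequences `S_cor` can overshoot `log2 N_h` slightly at short
lengths. When converting per-patient entropies to predictability bounds,
`S_cor` is clamped to `S_rnd` (i.e. `Π_cor ≥ 1/N_h`), which only ever
*lowers* the reported time-correlated predictability — a conservative
choice.

## The predictability bound

`Π` solves `S = H(Π) + (1−Π) log2(N−1)`. The right-hand side is the
entropy of the extremal source concentrating probability `Π` on one
symbol; it peaks at `Π = 1/N`, so the equation has two roots and the
*upper* bound is the root on the decreasing branch `Π ∈ [1/N, 1]`. The
root is found by `brentq` bisection to `xtol = 1e-12`; the residual of the
returned root is below `1e-9` bits (checked in the suite). Endpoints are
handled exactly (`Π(0,N)=1`, `Π(log2 N, N)=1/N`, `N=1 → Π=1`), and
entropies exceeding `log2 N` by at most a `1e-9` relative tolerance —
floating-point headroom, not a masking device — clamp to `1/N`; larger
overshoots raise an error.

For the individual analysis `N` is the patient's own `N_h` (the
uniform-guessing framing); for the collective analysis `N` is the
training-vocabulary size at the analysed hierarchy level, excluding the
reserved BOS/UNK tokens (the shared-alphabet framing). A fold's
cross-entropy can legitimately exceed `log2 N` (held-out loss is not
bounded by the alphabet); such values clamp to the `1/N` floor rather
than erroring, because they are meaningful "no better than chance"
outcomes.

`2^−S` is also reported as the *effective-alphabet* success probability; it
is a different, smaller quantity than the Fano bound and the two should
not be conflated.

## n-gram models

Counts are accumulated per order `1..n` with `n−1` BOS padding per
patient and no end-of-sequence token (histories are administrative
truncations, not completed utterances); BOS is never a predicted symbol
and never enters cross-entropy denominators. Out-of-vocabulary held-out
codes score as UNK, which carries the smoothing-reserved mass, keeping all
log-losses finite.

Smoothing is a documented knob because no single choice is canonical for
sparse clinical alphabets:

- **Witten–Bell** (default): interpolates each order with the next lower,
  with weight `T/(n+T)` (`T` = distinct continuation types); needs no
  held-out tuning and degrades gracefully on large sparse alphabets. The
  base distribution is uniform over the vocabulary including UNK.
- **Kneser–Ney**: interpolated absolute discounting (`d = 0.75`), with an
  add-one-smoothed continuation-count unigram as base so UNK keeps
  strictly positive mass.
- **Additive(δ)**: Lidstone at the top order only; mainly useful as a
  transparent oracle in tests.

Every fitted model's conditional distributions sum to one within `1e-9`
(swept in the suite), and cross-entropy matches an independent explicit
enumeration of the smoothing recursion on small alphabets.

Cross-validation partitions *patients* (not events) into `k = 10` folds by
a seeded permutation, trains on `k−1` folds and scores the held-out fold;
per-fold perplexity is identically `2^CE`.

**Stability.** Model trustworthiness across folds is summarised by the
percent change of joint n-gram probabilities between the reference fold
model and each other fold, `|p_a − p_b| / ((p_a+p_b)/2) × 100`
(symmetric-mean denominator), frequency-weighted by the n-gram's count in
the reference fold, reported as the weighted 95th percentile. Joint
probabilities factorise through each model's own smoothed conditionals so
all values are positive and comparable. The symmetric denominator and the
weighting are this package's choices; other definitions of "percent
change" would shift the percentile but not the cross-level ordering.

## Shuffle null models

- `D'` (within-patient): permutes each patient's codes uniformly at
  random; preserves per-patient multisets and lengths; timestamps keep
  their slots.
- `D''` (global swaps): repeatedly swaps a random code between two random
  patients; preserves lengths and the *global* multiset exactly. The
  default iteration count is 10× the total token count — coupon-collector
  scale mixing, exposed as a parameter since "large" is the only
  principled requirement.

The evaluation model is always trained on the unshuffled data and scored
on matched held-out patient sets from `D`, `D'`, `D''`; both shuffles are
byte-deterministic under a fixed seed.

The one-sided two-sample KS test (`a` stochastically smaller than `b`)
delegates to `scipy.stats.ks_2samp(alternative="greater")`; the direction
is an explicit argument throughout, and pairwise p-values are reported raw
with a Bonferroni column alongside (the headline claims use the raw
values, which at cohort sizes of thousands are far below any correction
threshold).

## Synthetic cohort generator

The generator emulates the *printed summary statistics* of the kind of
claims cohort this analysis targets, at desk scale, with these defaults:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 2000 | desk-scale stand-in for a ~5×10^5-patient cohort |
| `min_len` / `mean_len` | 20 / 31.16 | length floor and mean of the emulated cohort |
| length law | shifted negative binomial (r = 3) | overdispersed counts; only two moments are constrained |
| hierarchy | 10 × 4 × 5 × 6 = 1200 codes | same branching character as 19/186/1719/12462 at ~1/10 scale |
| `chronic_fraction` | 0.2 | chronic share of events |
| `chronic_persistence` | 0.6 | chronic codes arrive in episodes (flare-ups), not i.i.d. |
| `acute_personal` | 0.25 | recurrent acute codes cluster in the patient's dominant category |
| `zipf_exponent` | 1.0 | at the full 12 462-code scale, the top ~100 codes absorb ~50% of mass |
| `markov_order` | 1 | order of the chronic progression chains (2 available) |

Mechanism: each patient is assigned one cat3 code block ("their" disease
category). Chronic events step a small Markov chain over that block —
mostly exchangeable within the block with a mild directed cycle, because
real progression patterns are largely *alternate serialisations of the
same code set*. Acute events are i.i.d. Zipf draws over the full alphabet,
except that a fraction recurs within the patient's own block (recurrent
acute conditions). This minimal mechanism produces the phenomena the
analysis is designed to detect: order-dependence visible to `S_cor`,
collective structure captured at n-gram order 2 and exhausted beyond it,
mild degradation under `D'` and marked degradation under `D''`.

What the generator does **not** emulate: real ontology content, visit
block structure, care-pathway semantics, inter-patient correlation,
calendar effects, or coding-practice biases. Passing tests on synthetic
cohorts therefore validates the *estimators and pipeline*, not any claim
about a specific real EHR; the published magnitudes from half-million-
patient cohorts are not reproducible at this scale and are treated only as
qualitative patterns.

The synthetic text generator plays the natural-language foil: characters
of sentences assembled from a fixed lexicon of rigidly spelled words. For
such text, shuffling within sentences is nearly as destructive as global
shuffling (all structure is word-internal order), whereas for disease
sequences the two nulls separate — the signature that patient-level code
*sets*, not their serialisation, carry most of the information.

## Sizes and determinism

Every generator and analysis step is a pure function of its configuration
and seed; reports echo both. The acceptance script runs the full stack at
5000 synthetic patients, 5 CV folds, orders 1–3, 3-fold shuffle
evaluation, 10 000-token LZ recovery and 100 000-token n-gram recovery —
sizes chosen so the whole reproduction completes in well under a minute on
one core while leaving all qualitative conclusions stable across seeds.

## Known limitations

- `S_cor` on ~30-event histories carries substantial small-sample bias;
  only distributional comparisons are interpreted.
- The Fano bound is a theoretical ceiling over all predictors, not an
  achievable accuracy.
- n-gram models capture only adjacent-window dependence; gap-tolerant
  windows and longer-range structures are out of scope.
- Witten–Bell's reserved mass grows with context type diversity, which
  biases high-order cross-entropies upward on very sparse alphabets; this
  is why collective results are also reported at coarser hierarchy levels.
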