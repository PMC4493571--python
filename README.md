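# ehrpred

**Entropy and predictability bounds for clinical diagnosis-code sequences.**

A patient's electronic health record is, among other things, an ordered
sequence of diagnostic codes drawn from a hierarchical coding scheme such as
ICD-9. How predictable is that sequence — could any algorithm, in principle,
guess the next code? `ehrpred` answers this information-theoretically, for
epidemiologists and ML practitioners who want a ceiling on what sequence
models can achieve before building them.

## What it computes

**Individual analysis.** For each history `h` of length `n_h` with `N_h`
distinct codes, three entropy statistics (bits/symbol):

- random entropy `S_rnd = log2(N_h)` — uniform guessing;
- uncorrelated entropy `S_unc = -Σ_c p_c log2 p_c` — Shannon entropy of the
  empirical code frequencies;
- correlated entropy `S_cor = n_h log2(n_h) / Σ_k Γ_k` — the Lempel–Ziv
  match-length estimator, where `Γ_k` is the length of the shortest
  subsequence starting at position `k` not seen before `k`. Only this
  statistic is sensitive to temporal order.

Each entropy `S` converts to an upper bound `Π` on next-code predictability
by solving the Fano-type equality

```
S = H(Π) + (1 − Π) · log2(N − 1),   H(Π) = −Π log2 Π − (1−Π) log2(1−Π)
```

on the decreasing branch `Π ∈ [1/N, 1]`, so `Π(0, N) = 1` and
`Π(log2 N, N) = 1/N`.

**Collective analysis.** All patients share one code alphabet, so the cohort
can be treated as a single information source: smoothed n-gram models
(Witten–Bell by default; Kneser–Ney and additive selectable) of order 1–5,
scored by cross-entropy and perplexity under 10-fold cross-validation, plus a
fold-stability diagnostic on joint trigram probabilities.

**Null models.** Two seeded shuffles locate where the predictive information
lives: `D'` permutes codes within each patient (destroys order, keeps each
patient's code multiset) and `D''` swaps codes between random patients
(destroys the patient–code association, keeps the global multiset). A model
trained on the original data is evaluated on matched held-out slices of
`D`, `D'` and `D''`.

**Synthetic data.** The cohorts this method targets are private, so the
package ships a seeded generator emulating their printed summary statistics
(≥20 codes per patient, mean ≈31, hierarchical alphabet, Zipf-like marginals,
20% chronic share with block-structured progressions), Markov sources with
closed-form entropy rates for estimator validation, and a word-lexicon text
generator for the natural-language contrast.

## Worked example

```python
import numpy as np
import ehrpred as e
from ehrpred.ngram import collective_predictability

d, h = e.generate_cohort(e.CohortConfig(n_patients=2000, seed=1))
triples = e.entropy_profile(d)
pis = np.array(e.predictability_profile(triples))
print(f"mean Pi: rnd {100*pis[:,0].mean():.1f}%, "
      f"unc {100*pis[:,1].mean():.1f}%, cor {100*pis[:,2].mean():.1f}%")

res = e.cross_validate(d, orders=[1, 2, 3], k=5, seed=0)
for o, r in res.items():
    cp = collective_predictability(r)
    print(f"order {o}: cross-entropy {r.mean_cross_entropy:.2f} bits, "
          f"Pi = {100*cp['pi_mean']:.1f}%")
```

prints

```
mean Pi: rnd 5.0%, unc 20.9%, cor 36.7%
order 1: cross-entropy 9.06 bits, Pi = 18.1%
order 2: cross-entropy 8.72 bits, Pi = 22.2%
order 3: cross-entropy 9.07 bits, Pi = 17.9%
```

Reading: guessing uniformly among a patient's own codes succeeds 5% of the
time; knowing their code frequencies lifts the ceiling to ~21%; temporal
order lifts it to ~37%. Collectively, a bigram model beats the unigram
(order 1→2), while order 3 gains nothing — the temporal dependence structure
is exhausted at a window of two.

The same pipeline is available from the shell:

```bash
ehrpred simulate --n-patients 2000 --seed 1 --out cohort.jsonl --hierarchy hier.tsv
ehrpred report cohort.jsonl --hierarchy hier.tsv --levels full,cat2 \
    --orders 1:3 --folds 5 --seed 1 --outdir report/
```

Real datasets enter as JSONL (one patient per line:
`{"patient_id": ..., "events": [{"t": ..., "code": ...}, ...]}`) or via
`ehrpred convert` from long-format CSV, with the code hierarchy as a TSV
(`code  cat3  cat2  chapter`).

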