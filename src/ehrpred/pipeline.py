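"""Orchestration: individual analysis, collective analysis, shuffle suite.

Composes the estimator modules into the full study design — per-patient
entropy/predictability distributions at several hierarchy levels,
cross-validated n-gram bands, trigram stability, and the two shuffling
null experiments — with one-sided Kolmogorov–Smirnov comparisons
between distributions and seeded, fully reproducible outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CodeHierarchy, Level
from .corpus_io import SequenceDataset
from .entropy import entropy_profile
from .ngram import collective_predictability, cross_validate, stability
from .predictability import predictability_profile
from .shuffle import shuffle_experiment

__all__ = [
    "AnalysisReport",
    "ks_one_sided",
    "run_individual",
    "run_collective",
    "run_shuffle_suite",
    "run_report",
]

#: levels included in default reports; the chapter level exists but is
#: too coarse to be informative and is omitted by default
DEFAULT_LEVELS = (Level.FULL, Level.CAT_3, Level.CAT_2)


def ks_one_sided(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """One-sided two-sample KS test that ``a`` is stochastically smaller than ``b``.

    Returns ``(statistic, p_value)`` where the statistic is the largest
    exceedance of a's empirical CDF over b's, ``sup_x [F_a(x) - F_b(x)]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnalysisReport:
    """Container for the report sections; serialises to CSV/JSON."""

    config: dict = dc_field(default_factory=dict)
    individual: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    individual_ks: pd.DataFrame | None = None
    collective: pd.DataFrame | None = None
    stability: pd.DataFrame | None = None
    shuffles: pd.DataFrame | None = None

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(self.config, indent=2, sort_keys=True))
        for level, df in self.individual.items():
            df.to_csv(out / f"individual_{level}.csv", index=False)
        for name, df in (
            ("individual_ks", self.individual_ks),
            ("collective", self.collective),
            ("stability", self.stability),
            ("shuffles", self.shuffles),
        ):
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)


def run_individual(
    d: SequenceDataset,
    hierarchy: CodeHierarchy | None = None,
    levels: Sequence[Level] = DEFAULT_LEVELS,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-patient entropy and predictability at each hierarchy level.

    Returns ``(tables, ks_table)``: per level, a frame with one row per
    patient (entropies and Fano bounds), and the pairwise one-sided KS
    comparisons between the three statistics (raw p-values as the
    headline, Bonferroni-adjusted in an extra column).
    """
    tables: dict[str, pd.DataFrame] = {}
    ks_rows = []
    for level in levels:
        dl = d.project(hierarchy, level) if level is not d.level else d
        triples = entropy_profile(dl)
        pis = predictability_profile(triples)
        df = pd.DataFrame(
            {
                "patient_id": [t.patient_id for t in triples],
                "n_h": [t.n_h for t in triples],
                "n_distinct": [t.n_distinct for t in triples],
                "s_rnd": [t.s_rnd for t in triples],
                "s_unc": [t.s_unc for t in triples],
                "s_cor": [t.s_cor for t in triples],
                "pi_rnd": [p[0] for p in pis],
                "pi_unc": [p[1] for p in pis],
                "pi_cor": [p[2] for p in pis],
            }
        )
        tables[level.value] = df
        pairs = [("s_cor", "s_unc"), ("s_cor", "s_rnd"), ("s_unc", "s_rnd")]
        n_tests = len(pairs) * len(levels)
        for small, large in pairs:
            stat, p = ks_one_sided(df[small], df[large])
            ks_rows.append(
                {
                    "level": level.value,
                    "smaller": small,
                    "larger": large,
                    "ks_stat": stat,
                    "p_value": p,
                    "p_bonferroni": min(1.0, p * n_tests),
                }
            )
    return tables, pd.DataFrame(ks_rows)


def run_collective(
    d: SequenceDataset,
    hierarchy: CodeHierarchy | None = None,
    orders: Sequence[int] = (1, 2, 3, 4, 5),
    k: int = 10,
    levels: Sequence[Level] = DEFAULT_LEVELS,
    seed: int = 0,
    smoothing: str = "witten_bell",
    stability_order: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-validated n-gram bands per level and order, plus stability.

    Returns ``(cv_table, stability_table)``.  The cv table has one row
    per (level, order): mean/min/max fold cross-entropy and perplexity
    and the corresponding Fano bounds at the training-vocabulary
    alphabet size.  Stability is the frequency-weighted 95th percentile
    of joint-probability percent changes across fold models of
    ``stability_order`` (trigrams by default).
    """
    cv_rows = []
    stab_rows = []
    for level in levels:
        dl = d.project(hierarchy, level) if level is not d.level else d
        results, models = cross_validate(
            dl, orders, k=k, seed=seed, smoothing=smoothing, return_models=True
        )
        for order in orders:
            cv = results[order]
            ce = np.asarray(cv.fold_cross_entropy)
            pi = collective_predictability(cv)
            cv_rows.append(
                {
                    "level": level.value,
                    "order": order,
                    "n_symbols": cv.n_symbols,
                    "ce_mean": float(ce.mean()),
                    "ce_min": float(ce.min()),
                    "ce_max": float(ce.max()),
                    "ppl_mean": float((2.0 ** ce).mean()),
                    "pi_mean": pi["pi_mean"],
                    "pi_min": pi["pi_min"],
                    "pi_max": pi["pi_max"],
                }
            )
        if stability_order in models and len(models[stability_order]) >= 2:
            pct95, _, _ = stability(models[stability_order])
            stab_rows.append(
                {"level": level.value, "order": stability_order, "pct95_change": pct95}
            )
    return pd.DataFrame(cv_rows), pd.DataFrame(stab_rows)


def run_shuffle_suite(
    d: SequenceDataset,
    seed: int = 0,
    order: int = 2,
    k: int = 10,
    smoothing: str = "witten_bell",
    iterations: int | None = None,
) -> pd.DataFrame:
    """Order-2 model vs matched original/shuffled hold-outs, in percentage points.

    Returns the per-fold table from :func:`ehrpred.shuffle.shuffle_experiment`
    augmented with the mean Pi drop of each shuffled variant relative to
    the original hold-out, in percentage points (``delta_pp``).
    """
    table = shuffle_experiment(d, order=order, k=k, seed=seed, smoothing=smoothing,
                               iterations=iterations)
    base = table[table["variant"] == "V"].set_index("fold")["pi"]
    table["delta_pp"] = table.apply(
        lambda r: (base.loc[r["fold"]] - r["pi"]) * 100.0, axis=1
    )
    return table


def run_report(
    d: SequenceDataset,
    hierarchy: CodeHierarchy | None,
    seed: int = 0,
    orders: Sequence[int] = (1, 2, 3, 4, 5),
    k: int = 10,
    levels: Sequence[Level] = DEFAULT_LEVELS,
    smoothing: str = "witten_bell",
    config: dict | None = None,
) -> AnalysisReport:
    """Full pipeline: individual + collective + shuffle sections."""
    report = AnalysisReport(config=dict(config or {}, seed=seed, smoothing=smoothing))
    report.individual, report.individual_ks = run_individual(d, hierarchy, levels)
    report.collective, report.stability = run_collective(
        d, hierarchy, orders=orders, k=k, levels=levels, seed=seed, smoothing=smoothing
    )
    report.shuffles = run_shuffle_suite(d, seed=seed, k=min(k, 5), smoothing=smoothing)
    return report
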