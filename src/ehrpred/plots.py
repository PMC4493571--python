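"""Optional figures: entropy/predictability distributions and order bands.

Requires matplotlib (install the ``plot`` extra); everything else in the
package works without it.
"""

from __future__ import annotations

from pathlib import Path


def plot_individual_distributions(tables: dict, outdir) -> list[Path]:
    """Kernel-density-free histograms of the three entropy statistics and
    their Fano bounds, one figure per hierarchy level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for level, df in tables.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        for col, label in (("s_rnd", "rnd"), ("s_unc", "unc"), ("s_cor", "cor")):
            axes[0].hist(df[col], bins=40, histtype="step", density=True, label=label)
            axes[1].hist(df[f"pi_{label}"], bins=40, histtype="step", density=True, label=label)
        axes[0].set_xlabel("entropy (bits)")
        axes[1].set_xlabel("predictability bound $\\Pi$")
        for ax in axes:
            ax.set_ylabel("density")
            ax.legend(frameon=False)
        fig.suptitle(f"level: {level}")
        fig.tight_layout()
        p = out / f"individual_{level}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_collective_bands(cv_table, outdir, shuffles=None) -> Path:
    """Cross-entropy and predictability vs n-gram order, with fold bands;
    optionally overlays the shuffled-hold-out points at order 2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for level, grp in cv_table.groupby("level"):
        grp = grp.sort_values("order")
        axes[0].fill_between(grp["order"], grp["ce_min"], grp["ce_max"], alpha=0.25)
        axes[0].plot(grp["order"], grp["ce_mean"], marker="o", label=level)
        axes[1].fill_between(grp["order"], grp["pi_min"], grp["pi_max"], alpha=0.25)
        axes[1].plot(grp["order"], grp["pi_mean"], marker="o", label=level)
    if shuffles is not None:
        pts = shuffles.groupby("variant")[["cross_entropy", "pi"]].mean()
        for variant, row in pts.iterrows():
            axes[0].scatter([2], [row["cross_entropy"]], marker="x")
            axes[1].scatter([2], [row["pi"]], marker="x")
            axes[1].annotate(variant, (2, row["pi"]), fontsize=8)
    axes[0].set_xlabel("n-gram order")
    axes[0].set_ylabel("cross-entropy (bits/symbol)")
    axes[1].set_xlabel("n-gram order")
    axes[1].set_ylabel("predictability bound $\\Pi$")
    axes[1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    p = out / "collective_bands.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p
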