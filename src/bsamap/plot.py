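"""Three-panel scan figure: SNP-index of each bulk and Delta(SNP-index)
with its null confidence bands, per chromosome."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_scan(windows: pd.DataFrame, path: str | Path, title: str | None = None) -> None:
    """Render window means along the genome.

    Top/middle panels: mean SNP-index of bulk A (mutant) and bulk B
    (wild).  Bottom panel: mean Delta with the window-averaged 95% (green)
    and 99% (orange) null bounds when present.  One column per chromosome;
    output format follows the file suffix (PNG/SVG/PDF).
    """
    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(
        3, len(chroms), figsize=(4.5 * len(chroms), 7.5),
        sharex="col", sharey="row", squeeze=False,
    )
    for j, chrom in enumerate(chroms):
        sub = windows[(windows["chrom"] == chrom) & (windows["n_snps"] > 0)]
        mb = (sub["start"] + sub["end"]) / 2 / 1e6
        axes[0][j].plot(mb, sub["mean_indexA"], color="crimson", lw=0.8)
        axes[1][j].plot(mb, sub["mean_indexB"], color="crimson", lw=0.8)
        ax = axes[2][j]
        ax.plot(mb, sub["mean_delta"], color="crimson", lw=0.9)
        if "mean_ci95_hi" in sub.columns:
            ax.plot(mb, sub["mean_ci95_hi"], color="green", lw=0.6)
            ax.plot(mb, sub["mean_ci95_lo"], color="green", lw=0.6)
            ax.plot(mb, sub["mean_ci99_hi"], color="orange", lw=0.6)
            ax.plot(mb, sub["mean_ci99_lo"], color="orange", lw=0.6)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"{chrom} (Mb)")
        axes[0][j].set_title(chrom)
    axes[0][0].set_ylabel("SNP-index (bulk A)")
    axes[1][0].set_ylabel("SNP-index (bulk B)")
    axes[2][0].set_ylabel("Δ(SNP-index)")
    for row in axes[:2]:
        for ax in row:
            ax.set_ylim(0, 1)
    for ax in axes[2]:
        ax.set_ylim(-1, 1)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
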