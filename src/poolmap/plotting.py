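"""Genome-scan figure: per-chromosome panels of windowed mutant allele frequency."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .linkage import LinkageInterval


def plot_genome_scan(
    profile: pd.DataFrame,
    path: str | Path,
    interval: LinkageInterval | None = None,
) -> None:
    """One row of panels, one per chromosome, markers + sliding-window line.

    Raw folded frequencies are drawn as small marks, the window average as a
    line; the called interval (if any) is shaded on its chromosome.
    """
    chroms = list(pd.unique(profile["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(max(8, 0.9 * len(chroms)), 2.8),
        sharey=True, squeeze=False,
    )
    for ax, chrom in zip(axes[0], chroms):
        grp = profile[profile["chrom"] == chrom]
        ax.plot(grp["pos"] / 1e6, grp["folded_freq"], ".", ms=1.5,
                color="0.15", rasterized=True)
        ax.plot(grp["pos"] / 1e6, grp["window_freq"], "-", lw=1.2, color="crimson")
        if interval is not None and interval.chrom == chrom:
            ax.axvspan(interval.start_bp / 1e6, interval.end_bp / 1e6,
                       color="gold", alpha=0.4, zorder=0)
        ax.set_xlabel(chrom.replace("chr", ""), fontsize=7)
        ax.set_xticks([])
        ax.tick_params(labelsize=7)
        for side in ("top", "right"):
            ax.spines[side].set_visible(False)
    axes[0][0].set_ylabel("mutant allele frequency (folded)", fontsize=8)
    axes[0][0].set_ylim(0.45, 1.02)
    fig.suptitle("Sliding-window homozygosity scan", fontsize=9)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
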