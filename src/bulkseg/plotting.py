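"""Three-panel QTL-seq index plots.

One column per chromosome, three rows: FR-bulk SNP-index, SM-bulk
SNP-index (y in [0, 1], dashed line at 0.5) and Delta(SNP-index) (y in
[-1, 1]) with the null bands at both configured confidence levels.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

logger = logging.getLogger(__name__)

__all__ = ["plot_index_tracks"]


def plot_index_tracks(
    window_table,
    out_prefix,
    levels: Sequence[float] = (0.95, 0.99),
    formats: Sequence[str] = ("svg", "png"),
) -> dict:
    """Plot window means per chromosome; returns {format: path}.

    Chromosomes without windows are omitted with a warning.
    """
    chroms = [c for c, g in window_table.groupby("chrom", sort=False) if len(g)]
    if not chroms:
        logger.warning("no windows to plot")
        return {}
    ncol = len(chroms)
    fig, axes = plt.subplots(
        3, ncol, figsize=(4 * ncol, 7), sharex="col", sharey="row", squeeze=False
    )
    band_colors = {0.95: "red", 0.99: "green"}
    for j, chrom in enumerate(chroms):
        g = window_table[window_table["chrom"] == chrom]
        mid = (g["start"] + g["end"]) / 2 / 1e6
        axes[0][j].plot(mid, g["mean_fr"], lw=0.8, color="C0")
        axes[1][j].plot(mid, g["mean_sm"], lw=0.8, color="C1")
        axes[2][j].plot(mid, g["mean_delta"], lw=0.8, color="black")
        for ax in (axes[0][j], axes[1][j]):
            ax.axhline(0.5, ls="--", lw=0.5, color="grey")
        axes[2][j].axhline(0.0, ls="--", lw=0.5, color="grey")
        for level in levels:
            suffix = f"{round(level * 100):d}"
            lo, hi = f"ci_lo_{suffix}", f"ci_hi_{suffix}"
            if hi in g.columns:
                color = band_colors.get(level, "grey")
                axes[2][j].plot(mid, g[hi], lw=0.6, color=color)
                axes[2][j].plot(mid, g[lo], lw=0.6, color=color)
        axes[0][j].set_title(chrom)
        axes[2][j].set_xlabel("position (Mb)")
    axes[0][0].set_ylabel("FR SNP-index")
    axes[1][0].set_ylabel("SM SNP-index")
    axes[2][0].set_ylabel("Δ(SNP-index)")
    axes[0][0].set_ylim(0, 1)
    axes[1][0].set_ylim(0, 1)
    axes[2][0].set_ylim(-1, 1)
    fig.tight_layout()
    out = {}
    for fmt in formats:
        path = Path(f"{out_prefix}.{fmt}")
        fig.savefig(path, dpi=150)
        out[f"plot_{fmt}"] = path
    plt.close(fig)
    return out
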