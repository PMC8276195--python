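"""Minimal figure emission.

Plots are deliberately plain: every figure has a TSV twin written by the
pipeline, and these helpers only render that data.  The sequence logo is a
stacked-letter rendering of per-position information content, with T (not U)
as small RNA sequencing reports thymine.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from pirnakit.signatures import BASES, PositionFrequencyMatrix

_LOGO_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff8c00", "T": "#e31a1c"}


def plot_logo(matrix: PositionFrequencyMatrix, path: str | Path) -> None:
    """Information-content sequence logo (letters as scaled text glyphs)."""
    ic = matrix.information_content()
    fig, ax = plt.subplots(figsize=(0.5 * len(matrix.freq) + 1, 2.5))
    for pos in matrix.freq.index:
        heights = [(b, matrix.freq.loc[pos, b] * ic.loc[pos]) for b in BASES]
        heights.sort(key=lambda x: x[1])
        y = 0.0
        for base, h in heights:
            if h <= 0 or not np.isfinite(h):
                continue
            ax.text(
                pos,
                y + h / 2,
                base,
                ha="center",
                va="center",
                fontsize=18,
                color=_LOGO_COLORS[base],
                stretch="expanded",
                transform=ax.transData,
                clip_on=True,
                fontweight="bold",
                zorder=3,
            )
            y += h
    ax.set_xlim(0.4, len(matrix.freq) + 0.6)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(list(matrix.freq.index))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pingpong(overlap_counts, path: str | Path) -> None:
    """Barplot of the 5'-overlap histogram; the 10-nt bin is highlighted."""
    fig, ax = plt.subplots(figsize=(5, 3))
    colors = ["#e31a1c" if k == 10 else "#777777" for k in overlap_counts.index]
    ax.bar(overlap_counts.index, overlap_counts.to_numpy(), color=colors)
    ax.set_xlabel("5' overlap (nt)")
    ax.set_ylabel("weighted pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rle(rle_stats, path: str | Path) -> None:
    """Boxplot-style RLE diagnostic from precomputed quartiles."""
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(rle_stats)), 3))
    x = np.arange(len(rle_stats))
    ax.vlines(x, rle_stats["min"], rle_stats["max"], color="#999999", lw=1)
    ax.vlines(x, rle_stats["q1"], rle_stats["q3"], color="#1f78b4", lw=6)
    ax.plot(x, rle_stats["median"], "k_", markersize=10)
    ax.axhline(0.0, color="red", lw=0.8, ls="--")
    ax.set_xticks(x, rle_stats.index, rotation=90)
    ax.set_ylabel("RLE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
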