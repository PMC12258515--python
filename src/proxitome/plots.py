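"""Figure export: volcano plots, phospho-bias overlays, specificity heatmaps
and compartment bar charts. All functions write a file and return its path."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrichment import ContrastResult
from .phospho import BiasCurve
from .specificity import SpecificityMatrix


def volcano(result: ContrastResult, path: str | Path) -> Path:
    """Volcano plot with the dual-cutoff hits highlighted."""
    t = result.table
    fig, ax = plt.subplots(figsize=(5, 4))
    neglogp = -np.log10(t["p_value"])
    ax.scatter(t["log2fc"], neglogp, s=6, c="0.7", lw=0, label="all")
    hits = t["is_hit"]
    ax.scatter(t.loc[hits, "log2fc"], neglogp[hits], s=8, c="crimson", lw=0,
               label=f"hits (n={int(hits.sum())})")
    ax.axvline(result.lfc_cut, ls="--", c="0.4", lw=0.8)
    ax.axhline(-np.log10(result.p_cut), ls="--", c="0.4", lw=0.8)
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 p")
    ax.set_title(result.label)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def bias_overlay(curves: list[BiasCurve], path: str | Path) -> Path:
    """Overlay of phosphoprotein-fraction curves."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        ax.plot(curve.thresholds, curve.fraction, marker="o", ms=3,
                label=curve.contrast or None)
    ax.set_xlabel("log2 fold-change threshold")
    ax.set_ylabel("phosphoprotein fraction")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def matrix_heatmap(matrix: SpecificityMatrix, path: str | Path) -> Path:
    """Position × residue heatmap of a specificity matrix."""
    w = matrix.weights
    fig, ax = plt.subplots(figsize=(4, 6))
    vmax = float(np.abs(w.to_numpy()).max()) or 1.0
    im = ax.imshow(w.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(len(w.columns)), [str(c) for c in w.columns], fontsize=7)
    ax.set_yticks(range(len(w.index)), list(w.index), fontsize=7)
    ax.set_xlabel("position relative to pY")
    ax.set_title(matrix.domain)
    fig.colorbar(im, ax=ax, label="log2 enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def compartment_bars(profile: pd.DataFrame, path: str | Path) -> Path:
    """Per-variant matrix vs intermembrane-space mean log2fc bars."""
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(profile)), 4))
    x = np.arange(len(profile))
    ax.bar(x - 0.2, profile["mean_matrix"], width=0.4, label="matrix")
    ax.bar(x + 0.2, profile["mean_ims"], width=0.4, label="IMS")
    ax.set_xticks(x, profile["contrast"], rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("mean log2 fold-change")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
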