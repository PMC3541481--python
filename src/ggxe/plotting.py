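"""Diagnostic plots: eQTL position maps and hotspot histograms.

Plots are artifacts for eyeballing results, not analysis inputs; no numbers
are read back from them.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _cumulative_offsets(gmap) -> dict[int, float]:
    offsets = {}
    total = 0.0
    for c in gmap.chromosomes:
        offsets[c] = total
        total += gmap.bp[gmap.chrom_slice(c)].max() * 1.05
    return offsets


def plot_eqtl_positions(peaks: pd.DataFrame, annotation: pd.DataFrame, gmap, path):
    """Peak position (x) against gene position (y), genome-concatenated.

    Local eQTLs line up on the diagonal; trans hotspots show as vertical
    bands.  Positive additive effects (parent-1 allele up) and negative ones
    get distinct glyphs.
    """
    off = _cumulative_offsets(gmap)
    fig, ax = plt.subplots(figsize=(7, 7))
    if len(peaks):
        midx = [gmap.index_of(m) for m in peaks["peak_marker"]]
        x = np.array([gmap.bp[i] + off[int(gmap.chromosome[i])] for i in midx])
        gchrom = annotation.loc[peaks["gene_id"], "chromosome"].astype(int).to_numpy()
        gbp = annotation.loc[peaks["gene_id"], "bp"].to_numpy()
        y = np.array([bp + off[c] for bp, c in zip(gbp, gchrom)])
        pos = peaks["additive_effect"].to_numpy() > 0
        ax.scatter(x[pos], y[pos], marker="^", s=12, c="green", label="effect > 0")
        ax.scatter(x[~pos], y[~pos], marker="+", s=12, c="red", label="effect < 0")
        ax.legend(loc="upper left", fontsize=8)
    for c, o in off.items():
        ax.axvline(o, color="0.8", lw=0.5)
        ax.axhline(o, color="0.8", lw=0.5)
    ax.set_xlabel("eQTL peak position (genome bp)")
    ax.set_ylabel("gene position (genome bp)")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_hotspots(hotspot_table: pd.DataFrame, gmap, path):
    """Per-marker local/distant peak counts with the hotspot threshold line."""
    off = _cumulative_offsets(gmap)
    x = np.array(
        [bp + off[int(c)] for bp, c in zip(hotspot_table["bp"], hotspot_table["chromosome"])]
    )
    width = (x.max() - x.min()) / max(len(x), 1) * 0.8 if len(x) > 1 else 1.0
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.bar(x, hotspot_table["n_local"], width=width, color="purple", label="local")
    ax.bar(
        x,
        hotspot_table["n_distant"],
        width=width,
        bottom=hotspot_table["n_local"],
        color="steelblue",
        label="distant",
    )
    thr = float(hotspot_table["threshold"].iloc[0])
    ax.axhline(thr, color="red", lw=1, label=f"hotspot threshold = {thr:g}")
    for o in off.values():
        ax.axvline(o, color="0.8", lw=0.5)
    ax.set_xlabel("marker position (genome bp)")
    ax.set_ylabel("eQTL peaks")
    ax.legend(fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile_correlation_histogram(plasticity: pd.DataFrame, path, bin_width=0.05):
    """Four-panel histogram of profile correlations by eQTL class."""
    from .plasticity import EQTL_CLASSES

    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, cls in zip(axes.ravel(), EQTL_CLASSES):
        r = plasticity.loc[plasticity["eqtl_class"] == cls, "r"].dropna()
        ax.hist(r, bins=edges, color="gray")
        ax.set_title(f"{cls} (n={len(r)})", fontsize=9)
        ax.set_xlabel("profile correlation r")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
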