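"""Cross-experiment comparison of signed eQTL profiles.

The genotype-by-environment readout of a two-experiment design: each gene's
genome scan is condensed into a signed profile ``s_m = -log10(p_m) *
sign(a_m)`` (linkage strength carrying the direction of the allelic effect),
and the Pearson correlation of a gene's profiles across the two experiments
classifies its regulation as shared (r > 0.5), opposite (r < -0.5) or weak.
Called peaks are additionally matched pairwise between experiments to flag
overlapping eQTLs and, among those, eQTLs whose additive effects flip sign —
the hallmark of plastic, environment-dependent regulation.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import ScanResult
from .types import GeneticMap

EQTL_CLASSES = ("neither", "exp1_only", "exp2_only", "both")
CORR_CLASSES = ("strong_positive", "strong_negative", "weak")


def signed_profile(neg_log10_p: Sequence[float], effect: Sequence[float]) -> np.ndarray:
    """Per-marker ``-log10(p) * sign(additive effect)``; zero where p = 1."""
    s = np.asarray(neg_log10_p, dtype=float) * np.sign(np.asarray(effect, dtype=float))
    return s + 0.0  # normalise -0.0


def signed_profiles(scan: ScanResult) -> np.ndarray:
    """Genes x markers matrix of signed profiles for a whole scan."""
    return signed_profile(scan.neg_log10_p, scan.additive_effect)


def profile_correlation(s1: Sequence[float], s2: Sequence[float]) -> float:
    """Pearson r of two signed profiles on the same marker grid.

    Returns NaN when either profile is (numerically) constant or fewer than
    three markers are available — the correlation is then undefined and the
    gene is classed as weak.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("profiles have different marker grids")
    if s1.size < 3 or np.std(s1) == 0 or np.std(s2) == 0:
        return float("nan")
    return float(np.corrcoef(s1, s2)[0, 1])


def correlation_class(r: float) -> str:
    """Strict boundaries: strong only for r > 0.5 or r < -0.5."""
    if np.isnan(r):
        return "weak"
    if r > 0.5:
        return "strong_positive"
    if r < -0.5:
        return "strong_negative"
    return "weak"


def plasticity_table(
    scan1: ScanResult,
    scan2: ScanResult,
    peaks1: pd.DataFrame,
    peaks2: pd.DataFrame,
    labels: tuple[str, str] = ("exp1", "exp2"),
) -> pd.DataFrame:
    """Per-gene profile correlation and class, for genes scanned in both.

    ``eqtl_class`` stratifies genes by where they have called eQTLs
    (neither / exp1_only / exp2_only / both); genes present in only one
    scan are dropped.
    """
    common = [g for g in scan1.gene_ids if g in set(scan2.gene_ids)]
    has1 = set(peaks1["gene_id"]) if len(peaks1) else set()
    has2 = set(peaks2["gene_id"]) if len(peaks2) else set()
    S1 = signed_profiles(scan1)
    S2 = signed_profiles(scan2)
    i1 = {g: i for i, g in enumerate(scan1.gene_ids)}
    i2 = {g: i for i, g in enumerate(scan2.gene_ids)}
    rows = []
    for g in common:
        r = profile_correlation(S1[i1[g]], S2[i2[g]])
        in1, in2 = g in has1, g in has2
        eqtl_class = (
            "both" if in1 and in2 else
            "exp1_only" if in1 else
            "exp2_only" if in2 else "neither"
        )
        rows.append(
            {
                "gene_id": g,
                "r": r,
                "eqtl_class": eqtl_class,
                "corr_class": correlation_class(r),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "r", "eqtl_class", "corr_class"])


def match_eqtls(
    peaks1: pd.DataFrame,
    peaks2: pd.DataFrame,
    gmap: GeneticMap,
    max_peak_distance_cm: float = 10.0,
) -> pd.DataFrame:
    """Pair a gene's peaks across experiments by peak-to-peak distance.

    Greedy best-pair matching per gene: candidate pairs on the same
    chromosome with genetic distance <= ``max_peak_distance_cm`` (inclusive)
    are taken closest-first; matched pairs are ``overlapping`` and flagged
    ``opposite_effect`` when the two additive effects have strictly opposite
    signs.  Unmatched peaks are emitted with ``overlapping = False`` and the
    other experiment's columns missing.
    """
    rows = []
    genes = sorted(
        set(peaks1["gene_id"] if len(peaks1) else [])
        | set(peaks2["gene_id"] if len(peaks2) else [])
    )
    for g in genes:
        sub1 = peaks1[peaks1["gene_id"] == g] if len(peaks1) else peaks1
        sub2 = peaks2[peaks2["gene_id"] == g] if len(peaks2) else peaks2
        cand = []
        for i, r1 in sub1.iterrows():
            for j, r2 in sub2.iterrows():
                d = gmap.genetic_distance(r1["peak_marker"], r2["peak_marker"])
                if d <= max_peak_distance_cm:
                    cand.append((d, i, j))
        cand.sort(key=lambda t: t[0])
        used1: set = set()
        used2: set = set()
        for d, i, j in cand:
            if i in used1 or j in used2:
                continue
            used1.add(i)
            used2.add(j)
            e1 = float(sub1.loc[i, "additive_effect"])
            e2 = float(sub2.loc[j, "additive_effect"])
            rows.append(
                {
                    "gene_id": g,
                    "peak_marker_exp1": sub1.loc[i, "peak_marker"],
                    "peak_marker_exp2": sub2.loc[j, "peak_marker"],
                    "distance_cm": d,
                    "effect_exp1": e1,
                    "effect_exp2": e2,
                    "overlapping": True,
                    "opposite_effect": bool(e1 * e2 < 0),
                }
            )
        for i, r1 in sub1.iterrows():
            if i not in used1:
                rows.append(
                    {
                        "gene_id": g,
                        "peak_marker_exp1": r1["peak_marker"],
                        "peak_marker_exp2": pd.NA,
                        "distance_cm": np.nan,
                        "effect_exp1": float(r1["additive_effect"]),
                        "effect_exp2": np.nan,
                        "overlapping": False,
                        "opposite_effect": False,
                    }
                )
        for j, r2 in sub2.iterrows():
            if j not in used2:
                rows.append(
                    {
                        "gene_id": g,
                        "peak_marker_exp1": pd.NA,
                        "peak_marker_exp2": r2["peak_marker"],
                        "distance_cm": np.nan,
                        "effect_exp1": np.nan,
                        "effect_exp2": float(r2["additive_effect"]),
                        "overlapping": False,
                        "opposite_effect": False,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "peak_marker_exp1",
            "peak_marker_exp2",
            "distance_cm",
            "effect_exp1",
            "effect_exp2",
            "overlapping",
            "opposite_effect",
        ],
    )


def plasticity_summary(
    plasticity: pd.DataFrame,
    matches: pd.DataFrame | None = None,
    bin_width: float = 0.05,
) -> dict:
    """Counts and fractions per eQTL class x correlation class, plus an
    r histogram (binned at ``bin_width``) and overlap/opposite-effect totals."""
    counts = (
        plasticity.groupby(["eqtl_class", "corr_class"]).size().unstack(fill_value=0)
        .reindex(index=list(EQTL_CLASSES), columns=list(CORR_CLASSES), fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    r = plasticity["r"].dropna().to_numpy()
    hist, _ = np.histogram(r, bins=edges)
    out = {
        "counts": counts,
        "fractions": fractions,
        "histogram_edges": edges,
        "histogram_counts": hist,
    }
    if matches is not None and len(matches):
        out["n_overlapping"] = int(matches["overlapping"].sum())
        out["n_opposite_effect"] = int(matches["opposite_effect"].sum())
    return out
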