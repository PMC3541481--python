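"""Hotspot detection, exact enrichment tests and genomic bookkeeping.

A hotspot for transcript regulation (HTR) is a marker where many more eQTL
peaks co-locate than uniform placement would give.  The null here is a
uniform multinomial of the T observed peaks over the M markers, approximated
per marker by Poisson(T/M), with a Bonferroni-corrected tail cutoff across
markers.  The enrichment workhorse is the exact hypergeometric upper tail
computed in log space (no normal approximation), plus closed-interval
membership (NIL introgressions), flanking-marker binned counts, and the
t-test on a Pearson correlation of two binned genomic distributions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    k: int           # overlap observed
    n: int           # sample size drawn
    K: int           # successes in the population
    N: int           # population size
    p_value: float
    tail_mode: str   # "strict" (P[X > k]) or "inclusive" (P[X >= k])


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    p_value: float


def hotspot_scan(
    peaks: pd.DataFrame,
    gmap,
    alpha: float = 0.05,
    count_mode: str = "total",
) -> pd.DataFrame:
    """Count eQTL peaks per marker and flag hotspots.

    ``count_mode`` selects whether the total or only the distant peak count
    is tested.  The threshold is the smallest c with
    ``P(Poisson(T/M) >= c) <= alpha / M``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if len(peaks) == 0:
        raise ValueError("no peaks to scan")
    markers = list(gmap.marker_ids)
    counts = peaks.groupby("peak_marker").size().reindex(markers, fill_value=0)
    if "locality" in peaks.columns and peaks["locality"].notna().any():
        local = (
            peaks[peaks["locality"] == "local"]
            .groupby("peak_marker").size().reindex(markers, fill_value=0)
        )
        distant = (
            peaks[peaks["locality"] == "distant"]
            .groupby("peak_marker").size().reindex(markers, fill_value=0)
        )
    else:
        local = pd.Series(0, index=markers)
        distant = pd.Series(0, index=markers)
    tested = distant if count_mode == "distant" else counts
    T = int(tested.sum())
    M = len(markers)
    lam = T / M
    threshold = poisson_hotspot_threshold(lam, M, alpha)
    return pd.DataFrame(
        {
            "marker": markers,
            "chromosome": gmap.chromosome,
            "bp": gmap.bp,
            "n_local": local.to_numpy(),
            "n_distant": distant.to_numpy(),
            "n_total": counts.to_numpy(),
            "expected": lam,
            "threshold": threshold,
            "is_hotspot": tested.to_numpy() >= threshold,
        }
    )


def poisson_hotspot_threshold(lam: float, n_markers: int, alpha: float = 0.05) -> int:
    """Smallest count c with ``P(Poisson(lam) >= c) <= alpha / n_markers``."""
    target = alpha / n_markers
    c = max(int(stats.poisson.ppf(1.0 - target, lam)), 0)
    # sf(c-1) = P(X >= c); walk to the exact boundary
    while stats.poisson.sf(c - 1, lam) > target:
        c += 1
    while c > 0 and stats.poisson.sf(c - 2, lam) <= target:
        c -= 1
    return c


def _log_hypergeom_pmf(x: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_enrichment(
    k: int, n: int, K: int, N: int, tail_mode: str = "strict"
) -> EnrichmentResult:
    """Exact hypergeometric over-representation test, summed in log space.

    Draw ``n`` from a population of ``N`` containing ``K`` successes and
    observe ``k`` successes.  ``strict`` (default) returns P(X > k),
    ``inclusive`` P(X >= k); the strict tail matches the convention of the
    common statistical packages for over-representation bounds.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if k > min(n, K) or n > N or K > N:
        raise ValueError("inconsistent counts: need k <= min(n, K) and n, K <= N")
    if tail_mode not in ("strict", "inclusive"):
        raise ValueError(f"unknown tail_mode {tail_mode!r}")
    lo = k + 1 if tail_mode == "strict" else k
    lo = max(lo, max(0, n - (N - K)))
    hi = min(n, K)
    if lo > hi:
        p = 0.0
    else:
        x = np.arange(lo, hi + 1, dtype=float)
        p = float(np.exp(logsumexp(_log_hypergeom_pmf(x, N, K, n))))
        p = min(p, 1.0)
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=p, tail_mode=tail_mode)


def interval_membership(
    items: pd.DataFrame,
    intervals: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign items (chromosome, bp; 1-based) to closed [start, end] intervals.

    ``intervals`` needs columns chromosome, start, end, label (labels unique).
    Returns the items with a ``labels`` column (list of every containing
    interval) and the per-interval counts.
    """
    intervals = pd.DataFrame(intervals)
    if intervals["label"].duplicated().any():
        raise ValueError("interval labels must be unique")
    if (intervals["start"] > intervals["end"]).any():
        raise ValueError("interval start must be <= end")
    items = pd.DataFrame(items).copy()
    labels: list[list[str]] = []
    counts = {str(lab): 0 for lab in intervals["label"]}
    ichrom = intervals["chromosome"].to_numpy().astype(int)
    istart = intervals["start"].to_numpy().astype(int)
    iend = intervals["end"].to_numpy().astype(int)
    ilab = intervals["label"].to_numpy().astype(str)
    for _, row in items.iterrows():
        c, bp = int(row["chromosome"]), int(row["bp"])
        hit = (ichrom == c) & (istart <= bp) & (bp <= iend)
        labs = [str(l) for l in ilab[hit]]
        for l in labs:
            counts[l] += 1
        labels.append(labs)
    items["labels"] = labels
    return items, pd.Series(counts, name="count")


#: The two NIL introgression segments on chromosome 1 used as the default
#: interval set (approximate published bounds, in bp).
NIL_INTROGRESSIONS = pd.DataFrame(
    {
        "chromosome": [1, 1],
        "start": [5_000_000, 26_500_000],
        "end": [8_200_000, 30_400_000],
        "label": ["introgression_1", "introgression_2"],
    }
)


def binned_counts(
    gmap,
    positions: pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> pd.Series:
    """Count positions falling into each marker locus.

    The locus of a marker is the midpoint-to-midpoint region between its
    flanking markers; the first and last bins of a chromosome extend to the
    chromosome bounds.  Positions on chromosomes absent from the map are
    ignored with a logged warning.  Optional weights are summed instead of
    unit counts (use to correct for uneven sampling per locus).
    """
    positions = pd.DataFrame(positions).reset_index(drop=True)
    w = np.ones(len(positions)) if weights is None else np.asarray(weights, float)
    acc = np.zeros(gmap.n_markers)
    known = set(gmap.chromosomes)
    for chrom, sub in positions.groupby("chromosome"):
        chrom = int(chrom)
        if chrom not in known:
            logger.warning("positions on unmapped chromosome %s ignored", chrom)
            continue
        idx = gmap.chrom_slice(chrom)
        mbp = gmap.bp[idx].astype(float)
        mids = (mbp[:-1] + mbp[1:]) / 2.0
        which = np.searchsorted(mids, sub["bp"].to_numpy().astype(float))
        np.add.at(acc, idx[which], w[sub.index.to_numpy()])
    return pd.Series(acc, index=list(gmap.marker_ids))


def distribution_correlation(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of two binned genomic distributions with a t-test.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom,
    two-sided.  Perfectly collinear inputs cap at the smallest positive p.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 bins")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation for a constant vector")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, n=n, t_statistic=float("inf"), p_value=5e-324)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, t_statistic=float(t), p_value=max(p, 5e-324))
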