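"""Genome scans, permutation thresholds, peak calling and cis/trans labels.

The base statistic is single-marker regression ``y = mu + a * x + e`` with the
+1/-1 genotype coding, in which the slope ``a`` is exactly half the difference
between the two genotype-class means (the conventional additive effect;
``a > 0`` means the parent-1 / Ler allele increases expression) and the test
of ``a = 0`` is exactly the pooled two-sample t-test.  The whole genes x
markers scan therefore reduces to one matrix product, which is what makes
10,000-permutation genome-wide thresholds cheap.

A statsmodels-style front door is provided: build an :class:`EqtlScan` from an
expression dataset, genotypes and a map, ``fit()`` it to get an
:class:`EqtlScanResults`, then derive thresholds and call peaks from the
results object.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionDataset, GeneticMap, GenotypeMatrix

LN10 = np.log(10.0)

#: Cap for -log10(p) so that zero-residual fits stay finite.
DEFAULT_NEGLOG_CEILING = 300.0

#: Cofactor exclusion window (cM): markers this close to a cofactor are not
#: tested conditionally on it (the test would be against itself).
COFACTOR_EXCLUSION_CM = 10.0

PEAK_COLUMNS = [
    "gene_id",
    "chromosome",
    "peak_marker",
    "peak_neg_log10_p",
    "additive_effect",
    "interval_start",
    "interval_end",
    "locality",
]


@dataclass
class ScanResult:
    """Per-gene, per-marker p-values and signed additive effects."""

    gene_ids: np.ndarray
    marker_ids: np.ndarray
    p_value: np.ndarray          # genes x markers, in (0, 1]
    neg_log10_p: np.ndarray      # -log10(p), capped
    additive_effect: np.ndarray  # slope a; >0 = A/Ler allele raises expression

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = self._gene_index[gene_id]
        return self.p_value[i], self.neg_log10_p[i], self.additive_effect[i]

    def to_frame(self) -> pd.DataFrame:
        """Long format: gene, marker, p, neglog10p, effect."""
        g, m = np.meshgrid(
            np.arange(self.n_genes), np.arange(len(self.marker_ids)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids[g.ravel()],
                "marker": self.marker_ids[m.ravel()],
                "p_value": self.p_value.ravel(),
                "neg_log10_p": self.neg_log10_p.ravel(),
                "additive_effect": self.additive_effect.ravel(),
            }
        )


@dataclass
class ThresholdSet:
    """Genome-wide significance cutoffs in use for one experiment.

    ``final_neg_log10_threshold`` is ``-log10`` of the most stringent (i.e.
    smallest) of the permutation and FDR-derived p thresholds supplied.
    """

    alpha: float = 0.05
    n_permutations: int = 0
    permutation_p_threshold: float | None = None
    fdr_p_threshold: float | None = None

    @property
    def final_p_threshold(self) -> float:
        cands = [
            t for t in (self.permutation_p_threshold, self.fdr_p_threshold)
            if t is not None
        ]
        if not cands:
            raise ValueError("no threshold has been set")
        return min(cands)

    @property
    def final_neg_log10_threshold(self) -> float:
        return float(-np.log10(self.final_p_threshold))


def _scan_matrix(
    Y: np.ndarray, X: np.ndarray, ceiling: float = DEFAULT_NEGLOG_CEILING
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS of every gene (rows of Y) on every marker (cols of X).

    Returns (p, neg_log10_p, additive_effect), each genes x markers.  p is
    reconstructed as ``10**-neg_log10_p`` so the two views agree exactly even
    in the far tail (neg_log10_p is computed through the log survival
    function and capped at ``ceiling``).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    n = Y.shape[1]
    if X.shape[0] != n:
        raise ValueError("Y and X disagree on the number of lines")
    if n < 4:
        raise ValueError("need at least 4 lines")
    Xc = X - X.mean(axis=0, keepdims=True)
    Sxx = np.einsum("ij,ij->j", Xc, Xc)
    if np.any(Sxx == 0):
        bad = np.flatnonzero(Sxx == 0)
        raise ValueError(f"monomorphic marker at column(s) {bad.tolist()}")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Syy = np.einsum("ij,ij->i", Yc, Yc)
    Sxy = Yc @ Xc
    a = Sxy / Sxx
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = Sxy**2 / np.outer(Syy, Sxx)
        r2 = np.clip(r2, 0.0, 1.0)
        t = np.sqrt(r2 * df / (1.0 - r2))
    t = np.where(np.isnan(t), np.inf, t)  # r2 == 1 -> infinite t
    neglog = -(np.log(2.0) + stats.t.logsf(t, df)) / LN10
    neglog = np.minimum(neglog, ceiling)
    flat = Syy == 0
    if np.any(flat):  # constant gene: nothing to explain
        neglog[flat] = 0.0
        a[flat] = 0.0
    neglog = np.maximum(neglog, 0.0)
    p = 10.0 ** (-neglog)
    return p, neglog, a


def marker_regression(
    y: Sequence[float],
    x: Sequence[float],
    ceiling: float = DEFAULT_NEGLOG_CEILING,
) -> tuple[float, float, float]:
    """Single-marker additive model; equivalent to the pooled two-sample t-test.

    ``x`` must be +1/-1 with both genotype groups present.  Returns
    ``(p_value, neg_log10_p, additive_effect)`` where the additive effect is
    half the difference of the genotype-class means.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length vectors")
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]):
        raise ValueError("monomorphic marker")
    p, neglog, a = _scan_matrix(y[None, :], x[:, None], ceiling=ceiling)
    return float(p[0, 0]), float(neglog[0, 0]), float(a[0, 0])


def _conditional_test(
    y: np.ndarray, xm: np.ndarray, cof: np.ndarray, ceiling: float
) -> tuple[float, float, float]:
    """t-test of the marker coefficient in y ~ 1 + xm + cofactors."""
    n = len(y)
    D = np.column_stack([np.ones(n), xm, cof]) if cof.size else np.column_stack(
        [np.ones(n), xm]
    )
    k = D.shape[1]
    if n <= k:
        return 1.0, 0.0, 0.0
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dfres = n - rank
    s2 = resid @ resid / dfres if dfres > 0 else 0.0
    DtD_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(max(s2 * DtD_inv[1, 1], 0.0))
    a = float(coef[1])
    if se == 0.0:
        if np.isclose(a, 0.0):
            return 1.0, 0.0, 0.0
        return 10.0 ** (-ceiling), ceiling, a
    tval = abs(a) / se
    neglog = float(-(np.log(2.0) + stats.t.logsf(tval, dfres)) / LN10)
    neglog = min(max(neglog, 0.0), ceiling)
    return 10.0 ** (-neglog), neglog, a


def genome_scan(
    expr: ExpressionDataset,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    environment: str | None = None,
    cofactors: Mapping[str, Sequence[str]] | None = None,
    ceiling: float = DEFAULT_NEGLOG_CEILING,
) -> ScanResult:
    """Scan every gene against every marker in one environment.

    Replicate samples are averaged per line first; samples whose line is not
    genotyped (the parental pseudo-lines) are excluded from mapping.  If
    ``cofactors`` maps a gene to marker ids, that gene is re-scanned
    conditionally on the cofactor genotypes, and markers within
    ``COFACTOR_EXCLUSION_CM`` of any cofactor are skipped (p = 1).
    """
    means = expr.line_means(environment=environment)
    geno_lines = set(genotypes.line_ids)
    lines = [l for l in means.columns if l in geno_lines]
    if not lines:
        raise ValueError("no expression sample maps to a genotyped line")
    Y = means[lines].to_numpy()
    X = genotypes.numeric(lines)
    p, neglog, a = _scan_matrix(Y, X, ceiling=ceiling)
    result = ScanResult(expr.gene_ids, genotypes.marker_ids, p, neglog, a)

    if cofactors:
        cm = gmap.cm
        chrom = gmap.chromosome
        for gene, markers in cofactors.items():
            gi = result._gene_index[gene]
            y = Y[gi]
            cof_idx = [gmap.index_of(m) for m in markers]
            C = X[:, cof_idx]
            for mi in range(len(genotypes.marker_ids)):
                near = any(
                    chrom[mi] == chrom[ci] and abs(cm[mi] - cm[ci]) <= COFACTOR_EXCLUSION_CM
                    for ci in cof_idx
                )
                if near:
                    pv, nl, eff = 1.0, 0.0, 0.0
                else:
                    pv, nl, eff = _conditional_test(y, X[:, mi], C, ceiling)
                result.p_value[gi, mi] = pv
                result.neg_log10_p[gi, mi] = nl
                result.additive_effect[gi, mi] = eff
    return result


def select_cofactors(
    y: Sequence[float],
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    lines: Sequence[str] | None = None,
    max_cofactors: int = 5,
    entry_p: float = 1e-4,
    ceiling: float = DEFAULT_NEGLOG_CEILING,
) -> list[str]:
    """Greedy forward selection of marker cofactors for one trait.

    Repeatedly adds the marker with the smallest conditional p-value while it
    is below ``entry_p``, up to ``max_cofactors``; ties break deterministically
    by (chromosome, position).  This stands in for a full multiple-QTL
    cofactor search.
    """
    if max_cofactors < 0:
        raise ValueError("max_cofactors must be >= 0")
    y = np.asarray(y, dtype=float)
    X = genotypes.numeric(lines)
    order = np.lexsort((gmap.cm, gmap.chromosome))  # deterministic tie-break
    selected: list[int] = []
    while len(selected) < max_cofactors:
        best = None
        C = X[:, selected] if selected else np.empty((len(y), 0))
        for mi in order:
            if mi in selected:
                continue
            pv, _, _ = _conditional_test(y, X[:, mi], C, ceiling)
            if pv < entry_p and (best is None or pv < best[0]):
                best = (pv, mi)
        if best is None:
            break
        selected.append(best[1])
    return [str(genotypes.marker_ids[i]) for i in selected]


def permutation_threshold(
    expr: ExpressionDataset,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
    environment: str | None = None,
    genes: Sequence[str] | None = None,
) -> float:
    """Genome-wide p threshold by permutation of line labels.

    For each permutation a gene from the panel (round-robin over all genes by
    default) has its line labels shuffled against the fixed genotypes; the
    genome-wide minimum p over markers is recorded, and the empirical
    ``alpha`` quantile of those minima is returned on the p scale.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    means = expr.line_means(environment=environment)
    geno_lines = set(genotypes.line_ids)
    lines = [l for l in means.columns if l in geno_lines]
    Y = means[lines].to_numpy()
    if genes is not None:
        gidx = {g: i for i, g in enumerate(means.index)}
        Y = Y[[gidx[g] for g in genes]]
    X = genotypes.numeric(lines)
    n = Y.shape[1]
    df = n - 2
    Xc = X - X.mean(axis=0, keepdims=True)
    Sxx = np.einsum("ij,ij->j", Xc, Xc)

    rng = np.random.default_rng(seed)
    gene_of_perm = np.arange(n_permutations) % Y.shape[0]
    max_t = np.empty(n_permutations)
    pos = 0
    for g in range(Y.shape[0]):
        k = int(np.sum(gene_of_perm == g))
        if k == 0:
            continue
        y = Y[g] - Y[g].mean()
        syy = y @ y
        idx = np.argsort(rng.random((k, n)), axis=1)  # k random permutations
        Sxy = y[idx] @ Xc
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.clip(Sxy**2 / (syy * Sxx), 0.0, 1.0) if syy > 0 else np.zeros_like(Sxy)
            tmat = np.sqrt(r2 * df / (1.0 - r2))
        max_t[pos : pos + k] = np.nanmax(np.where(np.isnan(tmat), np.inf, tmat), axis=1)
        pos += k
    min_p = 2.0 * stats.t.sf(max_t, df)
    return float(np.quantile(min_p, alpha))


def call_peaks(
    scan: ScanResult,
    gmap: GeneticMap,
    neg_log10_threshold: float,
) -> pd.DataFrame:
    """Call eQTL peaks as maximal supra-threshold runs of adjacent markers.

    Per gene and chromosome, each maximal run of consecutive markers with
    ``neg_log10_p >= threshold`` yields one record whose peak is the marker
    with the largest score (leftmost on ties) and whose support interval is
    the run itself.
    """
    if neg_log10_threshold < 0:
        raise ValueError("threshold must be >= 0")
    chrom_slices = [(c, gmap.chrom_slice(c)) for c in gmap.chromosomes]
    marker_ids = scan.marker_ids
    above = scan.neg_log10_p >= neg_log10_threshold
    rows = []
    hit_genes = np.flatnonzero(above.any(axis=1))
    for gi in hit_genes:
        mask_g = above[gi]
        score_g = scan.neg_log10_p[gi]
        eff_g = scan.additive_effect[gi]
        for chrom, idx in chrom_slices:
            mask = mask_g[idx]
            if not mask.any():
                continue
            padded = np.concatenate([[False], mask, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for start, stop in zip(edges[::2], edges[1::2]):
                run = idx[start:stop]
                peak = run[np.argmax(score_g[run])]
                rows.append(
                    {
                        "gene_id": scan.gene_ids[gi],
                        "chromosome": int(chrom),
                        "peak_marker": marker_ids[peak],
                        "peak_neg_log10_p": float(score_g[peak]),
                        "additive_effect": float(eff_g[peak]),
                        "interval_start": marker_ids[run[0]],
                        "interval_end": marker_ids[run[-1]],
                        "locality": pd.NA,
                    }
                )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def classify_local_distant(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    gmap: GeneticMap,
    window_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Label each peak local (cis) or distant (trans).

    A peak is local iff it lies on the gene's own chromosome and within
    ``window_bp`` (inclusive) of the gene's physical position.
    """
    peaks = peaks.copy()
    missing = sorted(set(peaks["gene_id"]) - set(annotation.index))
    if missing:
        raise ValueError(f"genes without annotation: {missing}")
    if len(peaks) == 0:
        return peaks
    gene_chrom = annotation.loc[peaks["gene_id"], "chromosome"].to_numpy().astype(int)
    gene_bp = annotation.loc[peaks["gene_id"], "bp"].to_numpy().astype(int)
    midx = np.array([gmap.index_of(m) for m in peaks["peak_marker"]])
    same_chrom = gmap.chromosome[midx] == gene_chrom
    close = np.abs(gmap.bp[midx] - gene_bp) <= window_bp
    peaks["locality"] = np.where(same_chrom & close, "local", "distant")
    return peaks


def gene_locality_rollup(peaks: pd.DataFrame) -> pd.Series:
    """Per-gene counts of {only_local, only_distant, both} eQTL regulation."""
    if len(peaks) == 0:
        return pd.Series(0, index=["only_local", "only_distant", "both"])
    has = peaks.groupby("gene_id")["locality"].agg(
        lambda s: ("local" in set(s), "distant" in set(s))
    )
    cats = has.map(
        lambda t: "both" if t[0] and t[1] else ("only_local" if t[0] else "only_distant")
    )
    counts = cats.value_counts()
    return counts.reindex(["only_local", "only_distant", "both"], fill_value=0)


# -- statsmodels-style front door -----------------------------------------

class EqtlScan:
    """Model object: a genome scan of expression on RIL genotypes.

    Parameters
    ----------
    expression : ExpressionDataset
    genotypes : GenotypeMatrix
    gmap : GeneticMap
    environment : str, optional
        Restrict to one environment's samples (required when the dataset
        holds several).
    """

    def __init__(
        self,
        expression: ExpressionDataset,
        genotypes: GenotypeMatrix,
        gmap: GeneticMap,
        environment: str | None = None,
    ):
        envs = expression.environments
        if environment is None and len(envs) > 1:
            raise ValueError(f"dataset holds environments {envs}; pick one")
        self.expression = expression
        self.genotypes = genotypes
        self.gmap = gmap
        self.environment = environment if environment is not None else envs[0]

    def fit(
        self,
        cofactors: Mapping[str, Sequence[str]] | None = None,
        ceiling: float = DEFAULT_NEGLOG_CEILING,
    ) -> "EqtlScanResults":
        scan = genome_scan(
            self.expression,
            self.genotypes,
            self.gmap,
            environment=self.environment,
            cofactors=cofactors,
            ceiling=ceiling,
        )
        return EqtlScanResults(self, scan)


class EqtlScanResults:
    """Fitted genome scan with threshold derivation and peak bookkeeping."""

    def __init__(self, model: EqtlScan, scan: ScanResult):
        self.model = model
        self.scan = scan
        self.thresholds = ThresholdSet()
        self._peaks: pd.DataFrame | None = None

    def permutation_threshold(
        self, n_permutations: int = 10_000, alpha: float = 0.05, seed: int | None = 0
    ) -> float:
        """Churchill-Doerge style genome-wide threshold; stored on the result."""
        thr = permutation_threshold(
            self.model.expression,
            self.model.genotypes,
            self.model.gmap,
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed,
            environment=self.model.environment,
        )
        self.thresholds.alpha = alpha
        self.thresholds.n_permutations = n_permutations
        self.thresholds.permutation_p_threshold = thr
        return thr

    def fdr_threshold(
        self,
        nominal_fdr: float = 0.05,
        correction_factor: int = 5,
        r2_max: float = 0.95,
        pi0_mode="smoother",
    ) -> float | None:
        """Pooled-qvalue threshold on thinned markers (see significance module)."""
        from .significance import pooled_threshold, thin_markers

        kept = thin_markers(self.model.gmap, self.model.genotypes, r2_max=r2_max)
        cols = [int(np.flatnonzero(self.scan.marker_ids == m)[0]) for m in kept]
        pool = self.scan.p_value[:, cols].ravel()
        thr = pooled_threshold(
            pool,
            nominal_fdr=nominal_fdr,
            correction_factor=correction_factor,
            pi0_mode=pi0_mode,
        )
        self.thresholds.fdr_p_threshold = thr
        return thr

    def call_peaks(
        self,
        neg_log10_threshold: float | None = None,
        window_bp: int = 2_000_000,
    ) -> pd.DataFrame:
        """Call and (when annotation is present) classify eQTL peaks."""
        if neg_log10_threshold is None:
            neg_log10_threshold = self.thresholds.final_neg_log10_threshold
        peaks = call_peaks(self.scan, self.model.gmap, neg_log10_threshold)
        ann = self.model.expression.annotation
        if ann is not None and len(peaks):
            peaks = classify_local_distant(peaks, ann, self.model.gmap)
        self._peaks = peaks
        return peaks

    def summary(self) -> str:
        lines = [
            "eQTL genome scan",
            "================",
            f"environment        : {self.model.environment}",
            f"genes x markers    : {self.scan.n_genes} x {len(self.scan.marker_ids)}",
            f"mapped lines       : {self.model.genotypes.n_lines}",
        ]
        t = self.thresholds
        if t.permutation_p_threshold is not None:
            lines.append(
                f"permutation p thr  : {t.permutation_p_threshold:.3g} "
                f"(alpha={t.alpha}, {t.n_permutations} permutations)"
            )
        if t.fdr_p_threshold is not None:
            lines.append(f"FDR-derived p thr  : {t.fdr_p_threshold:.3g}")
        try:
            lines.append(f"final -log10(P) thr: {t.final_neg_log10_threshold:.2f}")
        except ValueError:
            pass
        if self._peaks is not None:
            lines.append(f"eQTL peaks         : {len(self._peaks)}")
            lines.append(
                f"genes with eQTL    : {self._peaks['gene_id'].nunique()}"
            )
            if self._peaks["locality"].notna().any():
                roll = gene_locality_rollup(self._peaks)
                lines.append(
                    "gene roll-up       : "
                    + ", ".join(f"{k}={v}" for k, v in roll.items())
                )
        return "\n".join(lines)
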