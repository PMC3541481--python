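"""Parental differential expression, heritability and transgression.

Three per-gene summaries of where expression variation comes from:

* differential expression between two groups of replicate samples (parents,
  or a NIL against its recurrent parent) by a pooled-variance linear-model
  t-test with Storey q-values over the full gene set;
* broad-sense heritability H^2 = Vg / (Vg + Ve), estimated either from the
  parental replicate ANOVA ("parents" mode) or from among-RIL-line variance
  with the pooled parental replicate variance as the error term ("ril" mode);
* transgression: the count of RIL lines whose expression lies above
  mu_max + 2*SD_max or below mu_min - 2*SD_min, where mu/SD summarise the
  higher- and lower-expressing parent's replicates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .significance import storey_qvalues
from .types import PARENT_A, PARENT_B, ExpressionDataset

LN10 = np.log(10.0)


@dataclass
class HeritabilityRecord:
    gene_id: str
    var_genetic: float
    var_error: float

    @property
    def h2(self) -> float:
        tot = self.var_genetic + self.var_error
        if tot <= 0:
            return 0.0
        return float(np.clip(self.var_genetic / tot, 0.0, 1.0))


@dataclass
class TransgressionRecord:
    gene_id: str
    mu_max: float
    sd_max: float
    mu_min: float
    sd_min: float
    n_above: int
    n_below: int
    n_min: int = 2

    @property
    def is_transgressive(self) -> bool:
        return (self.n_above + self.n_below) >= self.n_min


def _pooled_ttest(A: np.ndarray, B: np.ndarray, ceiling: float = 300.0):
    """Vectorised two-sided pooled-variance t-test per row.

    Returns (difference, p).  Rows where both groups are constant and equal
    get p = 1; zero pooled variance with a non-zero difference caps at the
    -log10 ceiling.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n1, n2 = A.shape[1], B.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    diff = m1 - m2
    ss = ((A - m1[:, None]) ** 2).sum(axis=1) + ((B - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sp2 = ss / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff) / denom
    neglog = np.where(
        denom == 0,
        np.where(np.isclose(diff, 0.0), 0.0, ceiling),
        -(np.log(2.0) + stats.t.logsf(np.where(denom == 0, 0.0, t), df)) / LN10,
    )
    neglog = np.clip(neglog, 0.0, ceiling)
    return diff, 10.0 ** (-neglog)


def differential_expression(
    values1: np.ndarray | pd.DataFrame,
    values2: np.ndarray | pd.DataFrame,
    gene_ids: Sequence[str] | None = None,
    pi0_mode="smoother",
) -> pd.DataFrame:
    """Per-gene two-group contrast with q-values over the whole gene set.

    ``values1`` / ``values2`` are genes x replicates.  ``difference`` is
    mean(group1) - mean(group2).
    """
    if isinstance(values1, pd.DataFrame) and gene_ids is None:
        gene_ids = list(values1.index)
    A = np.atleast_2d(np.asarray(values1, dtype=float))
    B = np.atleast_2d(np.asarray(values2, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("the two groups disagree on the number of genes")
    diff, p = _pooled_ttest(A, B)
    q = storey_qvalues(p, pi0_mode=pi0_mode).q
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(A.shape[0])]
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "mean_group1": A.mean(axis=1),
            "mean_group2": B.mean(axis=1),
            "difference": diff,
            "p_value": p,
            "q_value": q,
        }
    )


def parents_differential_expression(
    expr: ExpressionDataset,
    environment: str | None = None,
    parent1: str = PARENT_A,
    parent2: str = PARENT_B,
    pi0_mode="smoother",
) -> pd.DataFrame:
    """Convenience wrapper: parent-1 vs parent-2 replicates of a dataset."""
    A = expr.replicate_values(parent1, environment).to_numpy()
    B = expr.replicate_values(parent2, environment).to_numpy()
    return differential_expression(A, B, gene_ids=list(expr.gene_ids), pi0_mode=pi0_mode)


def broad_sense_heritability(
    groups: Mapping[str, Sequence[float]],
    mode: str = "parents",
    error_variance: float | None = None,
    gene_id: str = "",
) -> HeritabilityRecord:
    """H^2 for a single gene.

    parents mode
        One-way ANOVA over the replicate groups: Ve is the within-line
        (replicate) mean square, Vg the between-line variance component
        ``(MSB - MSW) / n0`` (floored at zero; n0 the balanced group size).
    ril mode
        ``groups`` holds per-line replicate values; the among-line variance
        of line means is the total, ``error_variance`` is Ve (supply it on
        the same line-mean scale, i.e. replicate variance divided by the
        replicates averaged per line), and Vg = total - Ve floored at zero.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if mode == "parents":
        sizes = np.array([a.size for a in arrays])
        if np.all(sizes < 2):
            raise ValueError("no replicate variance estimable (all groups size 1)")
        grand = np.concatenate(arrays).mean()
        ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
        ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
        k = len(arrays)
        n = int(sizes.sum())
        msb = ssb / (k - 1)
        msw = ssw / (n - k) if n > k else 0.0
        # balanced-design coefficient; reduces to the group size when equal
        n0 = (n - (sizes**2).sum() / n) / (k - 1)
        vg = max((msb - msw) / n0, 0.0)
        return HeritabilityRecord(gene_id, vg, msw)
    if mode == "ril":
        if error_variance is None:
            raise ValueError("ril mode needs the pooled parental error variance")
        means = np.array([a.mean() for a in arrays])
        total = float(np.var(means, ddof=1))
        vg = max(total - error_variance, 0.0)
        return HeritabilityRecord(gene_id, vg, float(error_variance))
    raise ValueError(f"unknown mode {mode!r}")


def heritability_table(
    expr: ExpressionDataset,
    mode: str = "ril",
    environment: str | None = None,
    parent1: str = PARENT_A,
    parent2: str = PARENT_B,
) -> pd.DataFrame:
    """Vectorised per-gene H^2 over a whole dataset.

    ril mode uses replicate-averaged RIL line means against the pooled
    parental replicate variance; parents mode uses the two parents' replicate
    groups only.
    """
    A = expr.replicate_values(parent1, environment).to_numpy()
    B = expr.replicate_values(parent2, environment).to_numpy()
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    n1, n2 = A.shape[1], B.shape[1]
    ve = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    if mode == "ril":
        ril_lines = [
            l for l in expr.samples["line"].unique() if l not in (parent1, parent2)
        ]
        means = expr.line_means(environment=environment, lines=ril_lines)
        total = means.to_numpy().var(axis=1, ddof=1)
        # line means average r replicates: put the replicate-level parental
        # error variance on the same (line-mean) scale before decomposing
        sheet = expr.samples
        if environment is not None:
            sheet = sheet[sheet["environment"] == environment]
        reps = sheet.loc[sheet["line"].isin(ril_lines)].groupby("line").size().mean()
        ve = ve / max(reps, 1.0)
        vg = np.maximum(total - ve, 0.0)
    elif mode == "parents":
        # balanced two-group ANOVA, vectorised
        grand = (n1 * A.mean(axis=1) + n2 * B.mean(axis=1)) / (n1 + n2)
        ssb = n1 * (A.mean(axis=1) - grand) ** 2 + n2 * (B.mean(axis=1) - grand) ** 2
        msb = ssb / 1.0
        n = n1 + n2
        n0 = (n - (n1**2 + n2**2) / n) / 1.0
        vg = np.maximum((msb - ve) / n0, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tot = vg + ve
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(tot > 0, np.clip(vg / tot, 0.0, 1.0), 0.0)
    return pd.DataFrame(
        {
            "gene_id": list(expr.gene_ids),
            "var_genetic": vg,
            "var_error": ve,
            "H2": h2,
        }
    )


def transgression_stats(
    ril_values: Sequence[float],
    parent1_values: Sequence[float],
    parent2_values: Sequence[float],
    n_min: int = 2,
    gene_id: str = "",
) -> TransgressionRecord:
    """Count RIL values beyond the parental mean +/- 2 SD envelope."""
    p1 = np.asarray(parent1_values, dtype=float)
    p2 = np.asarray(parent2_values, dtype=float)
    if p1.size < 2 or p2.size < 2:
        raise ValueError("both parents need at least 2 replicates")
    ril = np.asarray(ril_values, dtype=float)
    stats_ = sorted(
        [(p1.mean(), p1.std(ddof=1)), (p2.mean(), p2.std(ddof=1))], key=lambda t: t[0]
    )
    (mu_min, sd_min), (mu_max, sd_max) = stats_
    n_above = int(np.sum(ril > mu_max + 2.0 * sd_max))
    n_below = int(np.sum(ril < mu_min - 2.0 * sd_min))
    return TransgressionRecord(
        gene_id, mu_max, sd_max, mu_min, sd_min, n_above, n_below, n_min
    )


def transgression_table(
    expr: ExpressionDataset,
    environment: str | None = None,
    n_min: int = 2,
    parent1: str = PARENT_A,
    parent2: str = PARENT_B,
) -> pd.DataFrame:
    """Vectorised transgression counts per gene, on RIL line means."""
    P1 = expr.replicate_values(parent1, environment).to_numpy()
    P2 = expr.replicate_values(parent2, environment).to_numpy()
    ril_lines = [
        l for l in expr.samples["line"].unique() if l not in (parent1, parent2)
    ]
    R = expr.line_means(environment=environment, lines=ril_lines).to_numpy()
    mu1, sd1 = P1.mean(axis=1), P1.std(axis=1, ddof=1)
    mu2, sd2 = P2.mean(axis=1), P2.std(axis=1, ddof=1)
    hi_is_1 = mu1 >= mu2
    mu_max = np.where(hi_is_1, mu1, mu2)
    sd_max = np.where(hi_is_1, sd1, sd2)
    mu_min = np.where(hi_is_1, mu2, mu1)
    sd_min = np.where(hi_is_1, sd2, sd1)
    n_above = (R > (mu_max + 2 * sd_max)[:, None]).sum(axis=1)
    n_below = (R < (mu_min - 2 * sd_min)[:, None]).sum(axis=1)
    return pd.DataFrame(
        {
            "gene_id": list(expr.gene_ids),
            "mu_max": mu_max,
            "sd_max": sd_max,
            "mu_min": mu_min,
            "sd_min": sd_min,
            "n_above": n_above,
            "n_below": n_below,
            "is_transgressive": (n_above + n_below) >= n_min,
        }
    )
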