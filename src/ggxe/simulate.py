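"""Simulation of RIL populations and two-environment expression data.

The generator emulates a biparental recombinant inbred line study design:
a marker scaffold over a handful of chromosomes, RIL genotypes produced by a
chromosome-wise Markov chain whose switch probability between adjacent
markers is the selfing-RIL recombination fraction ``R = 2r / (1 + 2r)`` with
Haldane's ``r = (1 - exp(-2d/100)) / 2`` for a distance of ``d`` cM, and
per-gene expression values ``baseline + beta * genotype + noise`` with
environment-specific betas (including sign flips, the genotype-by-environment
scenario of interest).  Parents are encoded as pseudo-lines of constant
genotype so every downstream operation treats parents and RILs uniformly.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    GENO_A,
    GENO_B,
    PARENT_A,
    PARENT_B,
    EffectSpec,
    ExpressionDataset,
    GeneticMap,
    GenotypeMatrix,
    TruthTable,
)

DEFAULT_ENVIRONMENTS = ("GG1", "GG2")


def haldane_recombination(d_cm) -> np.ndarray | float:
    """Recombination fraction per meiosis at ``d`` cM (Haldane, no interference)."""
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def ril_switch_probability(d_cm) -> np.ndarray | float:
    """Probability that adjacent markers differ in a selfed RIL.

    In the infinite-selfing limit the map expands: the observable switch
    fraction between markers at recombination fraction ``r`` is
    ``R = 2r / (1 + 2r)`` (e.g. R = 0.1535 at 10 cM).
    """
    r = np.asarray(haldane_recombination(d_cm), dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return out if out.ndim else float(out)


def generate_map(
    n_chrom: int = 5,
    markers_per_chrom: int = 20,
    chrom_length_cm: float = 85.0,
    bp_per_cm: float = 250_000.0,
    seed: int | None = None,
) -> GeneticMap:
    """Equally spaced marker scaffold.

    Markers run from 0 to ``chrom_length_cm`` inclusive on every chromosome;
    physical positions are ``cm * bp_per_cm`` rounded to integer bp.  The
    ``seed`` argument is accepted for interface symmetry with the other
    generators but the construction is deterministic.
    """
    if n_chrom < 1 or markers_per_chrom < 2 or chrom_length_cm <= 0 or bp_per_cm <= 0:
        raise ValueError("map sizes must be positive (>=2 markers per chromosome)")
    rows = []
    for c in range(1, n_chrom + 1):
        cm = np.linspace(0.0, chrom_length_cm, markers_per_chrom)
        for i, pos in enumerate(cm, start=1):
            rows.append(
                {
                    "marker": f"m{c}_{i:02d}",
                    "chromosome": c,
                    "cm": float(pos),
                    "bp": int(round(pos * bp_per_cm)),
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def simulate_ril_genotypes(
    gmap: GeneticMap, n_lines: int, seed: int | None = 0
) -> GenotypeMatrix:
    """Marker-to-marker Markov simulation of fully inbred RIL genotypes.

    The first marker of each chromosome is A or B with probability 1/2; each
    subsequent marker switches parent with probability
    ``ril_switch_probability(d)`` for the inter-marker distance ``d``.  Only
    the marker-level correlation structure matters downstream, so no explicit
    crossover process is simulated.
    """
    if n_lines < 2:
        raise ValueError("need at least two lines")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        cm = gmap.cm[idx]
        switch_p = ril_switch_probability(np.diff(cm))
        g = rng.integers(0, 2, size=n_lines) * 2 - 1
        cols.append(g.copy())
        for p in switch_p:
            flip = rng.random(n_lines) < p
            g = np.where(flip, -g, g)
            cols.append(g.copy())
    num = np.column_stack(cols)
    codes = np.where(num > 0, GENO_A, GENO_B)
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(
        pd.DataFrame(codes, index=lines, columns=gmap.marker_ids)
    )


def random_gene_positions(
    gmap: GeneticMap, n_genes: int, seed: int | None = 0, prefix: str = "g"
) -> pd.DataFrame:
    """Place genes uniformly over the physical span of the map.

    Returns an annotation frame indexed by gene id with columns
    ``chromosome`` and ``bp``.
    """
    rng = np.random.default_rng(seed)
    chroms = np.asarray(gmap.chromosomes)
    lengths = np.array(
        [gmap.bp[gmap.chrom_slice(c)].max() for c in chroms], dtype=float
    )
    probs = lengths / lengths.sum()
    chosen = rng.choice(chroms, size=n_genes, p=probs)
    bp = (rng.random(n_genes) * lengths[np.searchsorted(chroms, chosen)]).astype(int)
    ids = [f"{prefix}{i + 1:05d}" for i in range(n_genes)]
    return pd.DataFrame({"chromosome": chosen, "bp": bp}, index=pd.Index(ids, name="gene_id"))


# -- architecture helpers --------------------------------------------------

def cis_spec(
    gene_id: str,
    gmap: GeneticMap,
    annotation: pd.DataFrame,
    beta_env1: float,
    beta_env2: float | None = None,
    baseline: float = 0.0,
    noise_sd: float = 1.0,
) -> EffectSpec:
    """Cis effect: the source marker is the one nearest the gene itself."""
    row = annotation.loc[gene_id]
    marker = gmap.nearest_marker(int(row["chromosome"]), int(row["bp"]))
    b2 = beta_env1 if beta_env2 is None else beta_env2
    return EffectSpec(gene_id, "cis", marker, beta_env1, b2, baseline, noise_sd)


def trans_spec(
    gene_id: str,
    source_marker: str,
    beta_env1: float,
    beta_env2: float | None = None,
    baseline: float = 0.0,
    noise_sd: float = 1.0,
) -> EffectSpec:
    b2 = beta_env1 if beta_env2 is None else beta_env2
    return EffectSpec(gene_id, "trans", source_marker, beta_env1, b2, baseline, noise_sd)


def null_spec(gene_id: str, baseline: float = 0.0, noise_sd: float = 1.0) -> EffectSpec:
    return EffectSpec(gene_id, "null", None, 0.0, 0.0, baseline, noise_sd)


def simulate_expression(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    architecture: Sequence[EffectSpec],
    environment: str,
    env_labels: Sequence[str] = DEFAULT_ENVIRONMENTS,
    ril_replicates: int = 3,
    parent_replicates: int = 9,
    noise_seed: int | None = 0,
    annotation: pd.DataFrame | None = None,
) -> tuple[ExpressionDataset, TruthTable]:
    """Simulate one environment's expression matrix from an effect architecture.

    Each sample of line *l* gets, for gene *g*,
    ``baseline_g + beta_g(environment) * x(l, source_g) + N(0, noise_sd_g)``.
    Parents enter as constant-genotype pseudo-lines (all A / all B) with
    ``parent_replicates`` samples each; RILs get ``ril_replicates`` samples.
    The returned :class:`TruthTable` records the full architecture and seed.
    """
    if environment not in env_labels:
        raise ValueError(f"unknown environment {environment!r}; labels {tuple(env_labels)}")
    rng = np.random.default_rng(noise_seed)
    marker_pos = {m: i for i, m in enumerate(genotypes.marker_ids)}
    for spec in architecture:
        if spec.source_marker is not None and spec.source_marker not in marker_pos:
            raise ValueError(
                f"gene {spec.gene_id}: unknown source marker {spec.source_marker!r}"
            )
        if spec.noise_sd <= 0:
            raise ValueError(f"gene {spec.gene_id}: noise_sd must be > 0")

    ril_lines = list(genotypes.line_ids)
    X = genotypes.numeric()  # lines x markers
    n_ril = len(ril_lines)

    # genotype value per (gene, line), parents appended as +1 / -1 columns
    betas = np.array([s.beta(environment, env_labels) for s in architecture])
    baselines = np.array([s.baseline for s in architecture])
    noise_sd = np.array([s.noise_sd for s in architecture])
    src = np.array(
        [marker_pos[s.source_marker] if s.source_marker is not None else 0
         for s in architecture]
    )
    xg = X[:, src].T  # genes x ril lines
    xg[np.array([s.source_marker is None for s in architecture])] = 0.0
    parent_cols = np.column_stack(
        [np.ones(len(architecture)), -np.ones(len(architecture))]
    )
    xg = np.hstack([xg, parent_cols])  # genes x (rils + 2 parents)

    sample_rows = []
    line_col_idx = []
    for j, line in enumerate(ril_lines + [PARENT_A, PARENT_B]):
        reps = ril_replicates if j < n_ril else parent_replicates
        for r in range(1, reps + 1):
            sample_rows.append(
                {"sample_id": f"{line}_{environment}_r{r}", "line": line,
                 "environment": environment, "replicate": r}
            )
            line_col_idx.append(j)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    line_col_idx = np.asarray(line_col_idx)

    mean = baselines[:, None] + betas[:, None] * xg[:, line_col_idx]
    values = mean + rng.normal(0.0, 1.0, size=mean.shape) * noise_sd[:, None]
    gene_ids = [s.gene_id for s in architecture]
    expr = ExpressionDataset(
        pd.DataFrame(values, index=gene_ids, columns=samples.index),
        samples,
        annotation=annotation,
    )
    truth = TruthTable(list(architecture), tuple(env_labels), noise_seed)
    return expr, truth


def simulate_null_dataset(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_genes: int,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    environment: str = DEFAULT_ENVIRONMENTS[0],
    ril_replicates: int = 1,
    parent_replicates: int = 2,
) -> tuple[ExpressionDataset, TruthTable]:
    """All-null expression (every beta zero): the calibration workhorse."""
    arch = [null_spec(f"null{i + 1:05d}", noise_sd=noise_sd) for i in range(n_genes)]
    return simulate_expression(
        genotypes,
        gmap,
        arch,
        environment=environment,
        ril_replicates=ril_replicates,
        parent_replicates=parent_replicates,
        noise_seed=seed,
    )
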