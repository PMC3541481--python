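"""TSV readers/writers and dataset validation.

One dialect everywhere: tab-separated with a header row, ``NA`` for missing,
floats at 6 significant digits, deterministic column order and row sort so
that two writes of the same records are byte-identical.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GENO_A,
    GENO_B,
    ExpressionDataset,
    GeneticMap,
    GenotypeMatrix,
    TruthTable,
)

FLOAT_FMT = "%.6g"


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic TSV write (6 significant digits, NA for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="NA")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


# -- genetic map -----------------------------------------------------------

def write_map(gmap: GeneticMap, path) -> None:
    write_table(gmap.frame, path)


def read_map(path) -> GeneticMap:
    frame = read_table(path)
    return GeneticMap(frame)  # constructor validates ordering/uniqueness


# -- genotypes -------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    frame = genotypes.codes.copy()
    frame.index.name = "line"
    write_table(frame, path, index=True)


def read_genotypes(path) -> GenotypeMatrix:
    frame = read_table(path, index_col=0)
    arr = frame.to_numpy().astype(str)
    bad = np.argwhere(~np.isin(arr, [GENO_A, GENO_B, "nan"]))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"genotype code {arr[i, j]!r} at line {frame.index[i]!r}, "
            f"marker {frame.columns[j]!r} (allowed: A, B, NA)"
        )
    return GenotypeMatrix(frame)


# -- expression ------------------------------------------------------------

def write_expression(expr: ExpressionDataset, values_path, samples_path,
                     annotation_path=None) -> None:
    values = expr.values.copy()
    values.index.name = "gene_id"
    write_table(values, values_path, index=True)
    samples = expr.samples.copy()
    samples.index.name = "sample_id"
    write_table(samples, samples_path, index=True)
    if annotation_path is not None and expr.annotation is not None:
        write_annotation(expr.annotation, annotation_path)


def read_expression(values_path, samples_path, annotation_path=None) -> ExpressionDataset:
    values = read_table(values_path, index_col=0)
    samples = read_table(samples_path, index_col=0)
    annotation = read_annotation(annotation_path) if annotation_path else None
    return ExpressionDataset(values, samples, annotation)


# -- gene annotation (BED-like: chrom, start, end, gene_id) ----------------

def write_annotation(annotation: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chromosome": annotation["chromosome"].astype(int),
            "start": annotation["bp"].astype(int),
            "end": annotation["bp"].astype(int),
            "gene_id": annotation.index,
        }
    )
    write_table(bed, path)


def read_annotation(path) -> pd.DataFrame:
    bed = read_table(path)
    if bed[["chromosome", "start", "gene_id"]].isna().any().any():
        raise ValueError("annotation file has missing chromosome/start/gene_id values")
    return pd.DataFrame(
        {
            "chromosome": bed["chromosome"].to_numpy().astype(int),
            "bp": bed["start"].to_numpy().astype(int),
        },
        index=pd.Index(bed["gene_id"].to_numpy(), name="gene_id"),
    )


# -- whole datasets --------------------------------------------------------

DATASET_FILES = {
    "map": "map.tsv",
    "genotypes": "genotypes.tsv",
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "annotation": "annotation.tsv",
    "truth": "truth.yaml",
}


def write_dataset(
    outdir,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    expr: ExpressionDataset | None = None,
    truth: TruthTable | None = None,
    suffix: str = "",
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(gmap, outdir / DATASET_FILES["map"])
    write_genotypes(genotypes, outdir / DATASET_FILES["genotypes"])
    if expr is not None:
        tag = f"{suffix}." if suffix else ""
        write_expression(
            expr,
            outdir / f"{tag}{DATASET_FILES['expression']}",
            outdir / f"{tag}{DATASET_FILES['samples']}",
            outdir / DATASET_FILES["annotation"] if expr.annotation is not None else None,
        )
    if truth is not None:
        truth.to_yaml(outdir / DATASET_FILES["truth"])


def load_dataset(
    map_path,
    genotype_path,
    expression_path,
    samples_path,
    annotation_path=None,
) -> tuple[GeneticMap, GenotypeMatrix, ExpressionDataset]:
    """Load and cross-validate a full dataset.

    Errors name the offending rows: unknown genotype codes, duplicate or
    unsorted markers, samples whose line is neither a parent nor genotyped,
    and genotype/map marker mismatches.
    """
    gmap = read_map(map_path)
    genotypes = read_genotypes(genotype_path)
    if list(genotypes.marker_ids) != list(gmap.marker_ids):
        raise ValueError("genotype matrix columns do not match the map's markers")
    expr = read_expression(expression_path, samples_path, annotation_path)
    known = set(genotypes.line_ids) | {"Ler", "Cvi"}
    orphans = sorted(set(expr.samples["line"]) - known)
    if orphans:
        raise ValueError(f"samples reference unknown lines: {orphans}")
    return gmap, genotypes, expr


def write_results(records: pd.DataFrame, path, sort_by=None) -> None:
    """Write an analysis record table with deterministic order."""
    frame = pd.DataFrame(records).copy()
    if sort_by is None:
        sort_by = [
            c for c in ("gene_id", "chromosome", "bp", "marker", "peak_marker")
            if c in frame.columns
        ]
    if sort_by:
        frame = frame.sort_values(sort_by, kind="stable")
    write_table(frame, path)
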