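"""Core data containers for RIL genetical-genomics analyses.

The objects here are thin, validated wrappers around :class:`pandas.DataFrame`
so that every downstream statistic can work on plain NumPy views.  The
population design they describe is a biparental recombinant inbred line (RIL)
cross: two fully inbred parents (by convention ``Ler``-like allele ``A`` and
``Cvi``-like allele ``B``), a marker scaffold with genetic (cM) and physical
(bp) coordinates, and log-scale expression measurements of genes across
replicated samples of the lines in one or more environments.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Conventional ids for the two parental pseudo-lines.
PARENT_A = "Ler"
PARENT_B = "Cvi"

#: Genotype codes.  ``A`` maps to +1 (parent-1 allele), ``B`` to -1.
GENO_A = "A"
GENO_B = "B"

GENO_NUMERIC = {GENO_A: 1.0, GENO_B: -1.0}


class GeneticMap:
    """Ordered marker scaffold: marker id, chromosome, cM and bp position.

    Markers must be unique, and both coordinates strictly increasing within
    each chromosome.
    """

    REQUIRED = ("marker", "chromosome", "cm", "bp")

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame).reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"genetic map is missing columns {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        frame["chromosome"] = frame["chromosome"].astype(int)
        frame["cm"] = frame["cm"].astype(float)
        frame["bp"] = frame["bp"].astype(int)
        dup = frame["marker"][frame["marker"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate marker ids: {sorted(set(dup))}")
        if (frame["chromosome"] < 1).any():
            raise ValueError("chromosome numbers must be >= 1")
        if (frame["cm"] < 0).any() or (frame["bp"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        for chrom, sub in frame.groupby("chromosome", sort=False):
            for col in ("cm", "bp"):
                v = sub[col].to_numpy()
                if np.any(np.diff(v) <= 0):
                    raise ValueError(
                        f"map not strictly increasing in {col} on chromosome {chrom}"
                    )
        self.frame = frame
        self._index = {m: i for i, m in enumerate(frame["marker"])}

    # -- basic accessors ---------------------------------------------------
    @property
    def marker_ids(self) -> np.ndarray:
        return self.frame["marker"].to_numpy()

    @property
    def chromosome(self) -> np.ndarray:
        return self.frame["chromosome"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.frame["cm"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.frame["bp"].to_numpy()

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.frame["chromosome"].unique())

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def index_of(self, marker: str) -> int:
        try:
            return self._index[marker]
        except KeyError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def chrom_slice(self, chromosome: int) -> np.ndarray:
        """Integer indices of the markers on one chromosome, in map order."""
        return np.flatnonzero(self.chromosome == chromosome)

    def genetic_distance(self, marker1: str, marker2: str) -> float:
        """|cM| distance; infinite across chromosomes."""
        i, j = self.index_of(marker1), self.index_of(marker2)
        if self.chromosome[i] != self.chromosome[j]:
            return float("inf")
        return abs(float(self.cm[i] - self.cm[j]))

    def nearest_marker(self, chromosome: int, bp: int) -> str:
        """Marker on ``chromosome`` physically closest to ``bp``."""
        idx = self.chrom_slice(int(chromosome))
        if idx.size == 0:
            raise ValueError(f"no markers on chromosome {chromosome}")
        k = idx[np.argmin(np.abs(self.bp[idx] - int(bp)))]
        return str(self.marker_ids[k])

    def __len__(self) -> int:
        return self.n_markers

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneticMap({self.n_markers} markers, "
            f"{len(self.chromosomes)} chromosomes)"
        )


class GenotypeMatrix:
    """Lines x markers genotype codes for an inbred biparental population.

    Codes are ``"A"`` / ``"B"`` (no heterozygotes: RILs are treated as fully
    inbred); missing values may appear as NaN after file loading.  The
    numeric view maps A -> +1 and B -> -1, the coding under which a positive
    additive effect means the parent-1 (Ler) allele increases expression.
    """

    def __init__(self, codes: pd.DataFrame):
        codes = pd.DataFrame(codes)
        bad = set(np.unique(codes.to_numpy().astype(str))) - {GENO_A, GENO_B, "nan"}
        if bad:
            raise ValueError(f"genotype codes outside {{A, B, NA}}: {sorted(bad)}")
        if codes.index.duplicated().any():
            raise ValueError("duplicate line ids in genotype matrix")
        self.codes = codes

    @property
    def line_ids(self) -> np.ndarray:
        return self.codes.index.to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.codes.columns.to_numpy()

    @property
    def n_lines(self) -> int:
        return len(self.codes)

    def numeric(self, lines: Sequence[str] | None = None) -> np.ndarray:
        """Float matrix (lines x markers) with A=+1, B=-1, NaN for missing."""
        codes = self.codes if lines is None else self.codes.loc[list(lines)]
        arr = codes.to_numpy().astype(object)
        out = np.full(arr.shape, np.nan)
        out[arr == GENO_A] = 1.0
        out[arr == GENO_B] = -1.0
        return out

    def allele_frequency_a(self) -> pd.Series:
        """Per-marker frequency of the A allele."""
        num = self.numeric()
        return pd.Series((np.nanmean(num, axis=0) + 1.0) / 2.0, index=self.marker_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_lines} lines x {len(self.marker_ids)} markers)"


@dataclass
class EffectSpec:
    """Generating model for one simulated gene.

    A gene's expression in a sample of line *l* is
    ``baseline + beta_env * x(l, source_marker) + N(0, noise_sd)`` with the
    +1/-1 genotype coding, so the parental contrast equals ``2 * beta_env``.
    ``kind`` is ``cis`` (source marker nearest the gene's own position),
    ``trans`` or ``null`` (both betas zero).  Sign-flip genotype-by-environment
    genes have ``beta_env1 * beta_env2 < 0``.
    """

    gene_id: str
    kind: str
    source_marker: str | None
    beta_env1: float
    beta_env2: float
    baseline: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("cis", "trans", "null"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.kind == "null":
            self.beta_env1 = 0.0
            self.beta_env2 = 0.0

    def beta(self, environment: str, env_labels: Sequence[str]) -> float:
        if environment == env_labels[0]:
            return self.beta_env1
        if environment == env_labels[1]:
            return self.beta_env2
        raise ValueError(f"unknown environment {environment!r}")


@dataclass
class TruthTable:
    """The full simulated effect architecture, for parameter-recovery tests."""

    effects: list[EffectSpec]
    environments: tuple[str, str] = ("GG1", "GG2")
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.effects])

    def genes_of_kind(self, kind: str) -> list[str]:
        return [e.gene_id for e in self.effects if e.kind == kind]

    def spec_for(self, gene_id: str) -> EffectSpec:
        for e in self.effects:
            if e.gene_id == gene_id:
                return e
        raise KeyError(gene_id)

    def to_yaml(self, path) -> None:
        doc = {
            "environments": list(self.environments),
            "seed": self.seed,
            "effects": [asdict(e) for e in self.effects],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TruthTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        effects = [EffectSpec(**e) for e in doc["effects"]]
        return cls(
            effects=effects,
            environments=tuple(doc["environments"]),
            seed=doc["seed"],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TruthTable)
            and self.effects == other.effects
            and tuple(self.environments) == tuple(other.environments)
            and self.seed == other.seed
        )


class ExpressionDataset:
    """Genes x samples log-expression with line/environment/replicate metadata.

    Parameters
    ----------
    values : DataFrame
        genes (index) x samples (columns), log-scale expression.
    samples : DataFrame
        indexed by sample id with columns ``line``, ``environment``,
        ``replicate``.
    annotation : DataFrame, optional
        indexed by gene id with columns ``chromosome`` and ``bp`` (the gene's
        physical position), needed for local/distant classification.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        annotation: pd.DataFrame | None = None,
    ):
        values = pd.DataFrame(values)
        samples = pd.DataFrame(samples)
        for col in ("line", "environment", "replicate"):
            if col not in samples.columns:
                raise ValueError(f"sample sheet is missing column {col!r}")
        if list(values.columns) != list(samples.index):
            raise ValueError("expression columns and sample sheet rows disagree")
        self.values = values
        self.samples = samples
        self.annotation = annotation if annotation is None else pd.DataFrame(annotation)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def n_genes(self) -> int:
        return len(self.values)

    @property
    def environments(self) -> list[str]:
        return sorted(self.samples["environment"].unique())

    def sample_ids(
        self, environment: str | None = None, lines: Iterable[str] | None = None
    ) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if environment is not None:
            mask &= self.samples["environment"] == environment
        if lines is not None:
            mask &= self.samples["line"].isin(set(lines))
        return list(self.samples.index[mask])

    def line_means(
        self,
        environment: str | None = None,
        lines: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        """Replicate-averaged expression, genes x lines.

        Replicates of the same line (within the selected environment) are
        averaged before any mapping statistic, mirroring pooling of plants
        per genotype.
        """
        cols = self.sample_ids(environment, lines)
        if not cols:
            raise ValueError("no samples match the requested selection")
        sub = self.values[cols]
        line_of = self.samples.loc[cols, "line"]
        return sub.T.groupby(line_of.to_numpy()).mean().T

    def replicate_values(self, line: str, environment: str | None = None) -> pd.DataFrame:
        """Genes x replicate-samples matrix for one line."""
        cols = self.sample_ids(environment, [line])
        if not cols:
            raise ValueError(f"no samples for line {line!r}")
        return self.values[cols]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionDataset({self.n_genes} genes x {self.values.shape[1]} samples, "
            f"environments={self.environments})"
        )
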