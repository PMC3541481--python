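"""End-to-end orchestration: simulate/load -> map -> thresholds -> reports.

All randomness flows from a single config seed fanned out per stage, so the
same config and seed reproduce identical result files.  Each run writes a
manifest (config hash, seed, per-stage row counts and timings) next to the
result tables.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hotspots as hs
from . import io as ggio
from . import plotting
from .mapping import EqtlScan
from .plasticity import match_eqtls, plasticity_table
from .popstats import (
    heritability_table,
    parents_differential_expression,
    transgression_table,
)
from .significance import estimate_fdr_inflation
from .simulate import (
    DEFAULT_ENVIRONMENTS,
    cis_spec,
    generate_map,
    null_spec,
    random_gene_positions,
    simulate_expression,
    simulate_ril_genotypes,
    trans_spec,
)
from .types import TruthTable

ALL_STAGES = [
    "simulate",
    "de",
    "heritability",
    "transgression",
    "scan",
    "permute",
    "fdr",
    "peaks",
    "hotspots",
    "plasticity",
    "plots",
]

DEFAULT_THRESHOLDS = {
    "alpha": 0.05,
    "n_permutations": 1000,
    "nominal_fdr": 0.05,
    "correction_factor": 5,
    "window_bp": 2_000_000,
    "max_peak_distance_cm": 10.0,
    "n_min": 2,
    "r2_max": 0.95,
}

DEFAULT_SIMULATION = {
    "n_lines": 160,
    "n_chrom": 5,
    "markers_per_chrom": 20,
    "chrom_length_cm": 85.0,
    "n_genes": 500,
    "n_cis": 40,
    "n_trans": 20,
    "n_flip": 20,
    "beta": 1.5,
    "noise_sd": 1.0,
    "ril_replicates": 3,
    "parent_replicates": 9,
}


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds or {})
        self.thresholds = merged
        if self.simulate is not None:
            sim = dict(DEFAULT_SIMULATION)
            sim.update(self.simulate)
            self.simulate = sim
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs' paths")
        if self.inputs is not None:
            missing = [p for p in self.inputs.values() if not Path(p).exists()]
            if missing:
                raise ValueError(f"input files do not exist: {missing}")

    def digest(self) -> str:
        doc = {
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": {k: str(v) for k, v in (self.inputs or {}).items()} or None,
            "thresholds": self.thresholds,
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path, outdir=None, seed=None) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PipelineConfig(
        seed=seed if seed is not None else int(doc.get("seed", 0)),
        outdir=outdir if outdir is not None else doc.get("outdir", "ggxe_results"),
        simulate=doc.get("simulate"),
        inputs=doc.get("inputs"),
        thresholds=doc.get("thresholds", {}),
    )


def _build_architecture(gmap, annotation, sim, rng):
    n = sim["n_genes"]
    n_cis, n_trans, n_flip = sim["n_cis"], sim["n_trans"], sim["n_flip"]
    if n_cis + n_trans + n_flip > n:
        raise ValueError("effect gene counts exceed n_genes")
    genes = list(annotation.index)
    beta, noise = sim["beta"], sim["noise_sd"]
    markers = list(gmap.marker_ids)
    arch = []
    for i, g in enumerate(genes):
        if i < n_cis:
            arch.append(cis_spec(g, gmap, annotation, beta, beta, noise_sd=noise))
        elif i < n_cis + n_trans:
            src = markers[rng.integers(0, len(markers))]
            arch.append(trans_spec(g, src, beta, beta, noise_sd=noise))
        elif i < n_cis + n_trans + n_flip:
            src = markers[rng.integers(0, len(markers))]
            arch.append(trans_spec(g, src, beta, -beta, noise_sd=noise))
        else:
            arch.append(null_spec(g, noise_sd=noise))
    return arch


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Execute the selected stages in dependency order; returns the outdir."""
    stages = list(ALL_STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {ALL_STAGES}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}
    ctx: dict = {}

    def record(name, n_rows, t0):
        manifest["stages"][name] = {
            "rows": int(n_rows),
            "seconds": round(time.time() - t0, 3),
        }

    def need(name, *deps):
        missing = [d for d in deps if d not in ctx]
        if missing:
            raise ValueError(f"stage {name!r} requires stage(s) {missing} to run first")

    envs = DEFAULT_ENVIRONMENTS

    if "simulate" in stages:
        t0 = time.time()
        sim = config.simulate
        if sim is None:
            raise ValueError("stage 'simulate' requires a 'simulate' config block")
        rng = np.random.default_rng([config.seed, 0])
        gmap = generate_map(
            sim["n_chrom"], sim["markers_per_chrom"], sim["chrom_length_cm"]
        )
        genotypes = simulate_ril_genotypes(
            gmap, sim["n_lines"], seed=int(rng.integers(2**31))
        )
        annotation = random_gene_positions(
            gmap, sim["n_genes"], seed=int(rng.integers(2**31))
        )
        arch = _build_architecture(gmap, annotation, sim, rng)
        exprs = {}
        truth = None
        for env in envs:
            exprs[env], truth = simulate_expression(
                genotypes,
                gmap,
                arch,
                environment=env,
                ril_replicates=sim["ril_replicates"],
                parent_replicates=sim["parent_replicates"],
                noise_seed=int(rng.integers(2**31)),
                annotation=annotation,
            )
        ctx.update(gmap=gmap, genotypes=genotypes, exprs=exprs, truth=truth)
        ggio.write_dataset(out / "data", gmap, genotypes, truth=truth)
        for env in envs:
            ggio.write_expression(
                exprs[env],
                out / "data" / f"{env}.expression.tsv",
                out / "data" / f"{env}.samples.tsv",
                out / "data" / "annotation.tsv",
            )
        record("simulate", sim["n_genes"], t0)
    elif config.inputs is not None:
        paths = config.inputs
        gmap, genotypes, expr = ggio.load_dataset(
            paths["map"],
            paths["genotypes"],
            paths["expression"],
            paths["samples"],
            paths.get("annotation"),
        )
        exprs = {env: expr for env in expr.environments}
        envs = tuple(expr.environments)
        ctx.update(gmap=gmap, genotypes=genotypes, exprs=exprs, truth=None)

    if "de" in stages:
        t0 = time.time()
        need("de", "exprs")
        frames = []
        for env in envs:
            de = parents_differential_expression(ctx["exprs"][env], environment=env)
            de.insert(0, "environment", env)
            frames.append(de)
        de_all = pd.concat(frames, ignore_index=True)
        ggio.write_results(de_all, out / "parents_de.tsv", sort_by=["environment", "gene_id"])
        ctx["de"] = de_all
        record("de", len(de_all), t0)

    if "heritability" in stages:
        t0 = time.time()
        need("heritability", "exprs")
        frames = []
        for env in envs:
            for mode in ("parents", "ril"):
                h = heritability_table(ctx["exprs"][env], mode=mode, environment=env)
                h.insert(0, "mode", mode)
                h.insert(0, "environment", env)
                frames.append(h)
        h_all = pd.concat(frames, ignore_index=True)
        ggio.write_results(
            h_all, out / "heritability.tsv", sort_by=["environment", "mode", "gene_id"]
        )
        ctx["heritability"] = h_all
        record("heritability", len(h_all), t0)

    if "transgression" in stages:
        t0 = time.time()
        need("transgression", "exprs")
        frames = []
        for env in envs:
            tg = transgression_table(
                ctx["exprs"][env], environment=env, n_min=int(thr["n_min"])
            )
            tg.insert(0, "environment", env)
            frames.append(tg)
        tg_all = pd.concat(frames, ignore_index=True)
        ggio.write_results(
            tg_all, out / "transgression.tsv", sort_by=["environment", "gene_id"]
        )
        ctx["transgression"] = tg_all
        record("transgression", len(tg_all), t0)

    if "scan" in stages:
        t0 = time.time()
        need("scan", "exprs")
        results = {}
        for env in envs:
            model = EqtlScan(ctx["exprs"][env], ctx["genotypes"], ctx["gmap"], env)
            results[env] = model.fit()
        ctx["scans"] = results
        n = sum(r.scan.n_genes for r in results.values())
        record("scan", n, t0)

    if "permute" in stages:
        t0 = time.time()
        need("permute", "scans")
        for i, env in enumerate(envs):
            ctx["scans"][env].permutation_threshold(
                n_permutations=int(thr["n_permutations"]),
                alpha=float(thr["alpha"]),
                seed=int(np.random.default_rng([config.seed, 1, i]).integers(2**31)),
            )
        record("permute", int(thr["n_permutations"]) * len(envs), t0)

    if "fdr" in stages:
        t0 = time.time()
        need("fdr", "scans")
        for env in envs:
            ctx["scans"][env].fdr_threshold(
                nominal_fdr=float(thr["nominal_fdr"]),
                correction_factor=int(thr["correction_factor"]),
                r2_max=float(thr["r2_max"]),
            )
        record("fdr", len(envs), t0)

    if "peaks" in stages:
        t0 = time.time()
        need("peaks", "scans")
        frames = []
        for env in envs:
            res = ctx["scans"][env]
            peaks = res.call_peaks(window_bp=int(thr["window_bp"]))
            peaks.insert(0, "environment", env)
            frames.append(peaks)
        peaks_all = pd.concat(frames, ignore_index=True)
        ggio.write_results(
            peaks_all, out / "eqtl_peaks.tsv", sort_by=["environment", "gene_id", "chromosome"]
        )
        thr_rows = []
        for env in envs:
            t = ctx["scans"][env].thresholds
            thr_rows.append(
                {
                    "environment": env,
                    "alpha": t.alpha,
                    "permutation_p_threshold": t.permutation_p_threshold,
                    "fdr_p_threshold": t.fdr_p_threshold,
                    "final_neg_log10_threshold": t.final_neg_log10_threshold,
                }
            )
        ggio.write_results(pd.DataFrame(thr_rows), out / "thresholds.tsv", sort_by=["environment"])
        ctx["peaks"] = {
            env: f.drop(columns="environment") for env, f in zip(envs, frames)
        }
        record("peaks", len(peaks_all), t0)

    if "hotspots" in stages:
        t0 = time.time()
        need("hotspots", "peaks")
        frames = []
        for env in envs:
            if len(ctx["peaks"][env]) == 0:
                continue
            ht = hs.hotspot_scan(ctx["peaks"][env], ctx["gmap"], alpha=float(thr["alpha"]))
            ht.insert(0, "environment", env)
            frames.append(ht)
        ht_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        ggio.write_results(ht_all, out / "hotspots.tsv", sort_by=["environment", "marker"])
        ctx["hotspots"] = frames
        record("hotspots", len(ht_all), t0)

    if "plasticity" in stages:
        t0 = time.time()
        need("plasticity", "scans", "peaks")
        if len(envs) < 2:
            raise ValueError("plasticity needs two environments")
        e1, e2 = envs[0], envs[1]
        table = plasticity_table(
            ctx["scans"][e1].scan,
            ctx["scans"][e2].scan,
            ctx["peaks"][e1],
            ctx["peaks"][e2],
        )
        matches = match_eqtls(
            ctx["peaks"][e1],
            ctx["peaks"][e2],
            ctx["gmap"],
            max_peak_distance_cm=float(thr["max_peak_distance_cm"]),
        )
        ggio.write_results(table, out / "plasticity.tsv", sort_by=["gene_id"])
        ggio.write_results(matches, out / "eqtl_matches.tsv", sort_by=["gene_id"])
        ctx["plasticity"] = table
        record("plasticity", len(table), t0)

    if "plots" in stages:
        t0 = time.time()
        need("plots", "peaks")
        ann = ctx["exprs"][envs[0]].annotation
        for env in envs:
            if ann is not None:
                plotting.plot_eqtl_positions(
                    ctx["peaks"][env], ann, ctx["gmap"], out / f"eqtl_map_{env}.png"
                )
        if ctx.get("hotspots"):
            for ht in ctx["hotspots"]:
                env = ht["environment"].iloc[0]
                plotting.plot_hotspots(ht, ctx["gmap"], out / f"hotspots_{env}.png")
        if "plasticity" in ctx:
            plotting.plot_profile_correlation_histogram(
                ctx["plasticity"], out / "plasticity_histogram.png"
            )
        record("plots", 0, t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
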