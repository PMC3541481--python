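"""Hotspot thresholds, exact hypergeometric tails, intervals and correlations."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ggxe import (
    NIL_INTROGRESSIONS,
    binned_counts,
    call_peaks,
    classify_local_distant,
    distribution_correlation,
    genome_scan,
    hotspot_scan,
    hypergeom_enrichment,
    interval_membership,
    null_spec,
    permutation_threshold,
    poisson_hotspot_threshold,
    random_gene_positions,
    simulate_expression,
    trans_spec,
)


def exact_hypergeom_tail(k, n, K, N, strict=True):
    """Rational-arithmetic oracle for the upper hypergeometric tail."""
    lo = k + 1 if strict else k
    total = Fraction(0)
    for x in range(max(lo, max(0, n - (N - K))), min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return total


class TestHypergeom:
    def test_small_case_enumeration(self):
        res = hypergeom_enrichment(3, 4, 5, 10)
        assert res.p_value == pytest.approx(5 / 210, rel=1e-12)
        inc = hypergeom_enrichment(3, 4, 5, 10, tail_mode="inclusive")
        assert inc.p_value == pytest.approx(55 / 210, rel=1e-12)

    def test_degenerate_population_all_successes(self):
        res = hypergeom_enrichment(4, 4, 10, 10)
        assert res.p_value == 0.0

    def test_exhaustive_against_rational_enumeration(self):
        """Log-space tail vs exact fractions over all configurations N <= 60."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k_max = min(n, K)
            k = int(rng.integers(max(0, n - (N - K)), k_max + 1))
            for strict in (True, False):
                got = hypergeom_enrichment(
                    k, n, K, N, tail_mode="strict" if strict else "inclusive"
                ).p_value
                want = float(exact_hypergeom_tail(k, n, K, N, strict=strict))
                assert got == pytest.approx(want, abs=1e-12, rel=1e-10)

    def test_strict_plus_pmf_equals_inclusive(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            N = int(rng.integers(5, 61))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n - (N - K)), min(n, K) + 1))
            strict = hypergeom_enrichment(k, n, K, N).p_value
            inclusive = hypergeom_enrichment(k, n, K, N, tail_mode="inclusive").p_value
            pmf = stats.hypergeom.pmf(k, N, K, n)
            assert strict + pmf == pytest.approx(inclusive, abs=1e-12)

    def test_log_space_agrees_with_rationals_at_larger_n(self):
        got = hypergeom_enrichment(120, 400, 500, 2000).p_value
        want = float(exact_hypergeom_tail(120, 400, 500, 2000))
        assert got == pytest.approx(want, rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_enrichment(1, 5, 11, 10)


class TestHotspotScan:
    def test_poisson_threshold_worked_example(self):
        # T=100 peaks over M=50 markers: lambda=2, Bonferroni target 0.001
        assert poisson_hotspot_threshold(2.0, 50, 0.05) == 9
        assert stats.poisson.sf(8, 2.0) <= 0.001 < stats.poisson.sf(7, 2.0)

    def test_single_loaded_marker_is_the_only_hotspot(self, gmap):
        m = str(gmap.marker_ids[10])
        peaks = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "chromosome": 1,
                "peak_marker": m,
                "peak_neg_log10_p": 5.0,
                "additive_effect": 1.0,
                "interval_start": m,
                "interval_end": m,
                "locality": "distant",
            }
        )
        table = hotspot_scan(peaks, gmap, alpha=0.05)
        assert table["is_hotspot"].sum() == 1
        assert table.loc[table["marker"] == m, "is_hotspot"].iloc[0]

    def test_uniform_placement_rarely_flagged(self, gmap):
        rng = np.random.default_rng(9)
        markers = list(gmap.marker_ids)
        flagged = 0
        for _ in range(200):
            placement = rng.integers(0, 100, size=40)
            peaks = pd.DataFrame(
                {
                    "gene_id": [f"g{j}" for j in range(40)],
                    "chromosome": [int(gmap.chromosome[i]) for i in placement],
                    "peak_marker": [markers[i] for i in placement],
                    "peak_neg_log10_p": 5.0,
                    "additive_effect": 1.0,
                    "interval_start": [markers[i] for i in placement],
                    "interval_end": [markers[i] for i in placement],
                    "locality": "distant",
                }
            )
            flagged += hotspot_scan(peaks, gmap, alpha=0.05)["is_hotspot"].any()
        assert flagged <= 10  # Bonferroni bound: 5% of runs

    def test_trans_hotspot_detected_through_full_pipeline(self, gmap, geno160):
        """A 30-target trans band survives scan -> peaks -> hotspot_scan."""
        markers = list(gmap.marker_ids)
        hot = markers[37]
        ann = random_gene_positions(gmap, 300, seed=5)
        genes = list(ann.index)
        arch = [trans_spec(g, hot, 1.5, noise_sd=1.0) for g in genes[:30]]
        arch += [null_spec(g) for g in genes[30:]]
        expr0, _ = simulate_expression(
            geno160, gmap, arch, "GG2", ril_replicates=1, parent_replicates=2,
            noise_seed=0, annotation=ann,
        )
        nl_thr = -np.log10(
            permutation_threshold(expr0, geno160, gmap, n_permutations=1000, seed=3)
        )
        flagged = 0
        for rep in range(100):
            expr, _ = simulate_expression(
                geno160, gmap, arch, "GG2", ril_replicates=1, parent_replicates=2,
                noise_seed=1000 + rep, annotation=ann,
            )
            scan = genome_scan(expr, geno160, gmap)
            peaks = classify_local_distant(call_peaks(scan, gmap, nl_thr), ann, gmap)
            table = hotspot_scan(peaks, gmap, alpha=0.05)
            flagged += bool(table.loc[table["marker"] == hot, "is_hotspot"].iloc[0])
        assert flagged >= 95


class TestIntervalMembership:
    def test_published_introgression_containment(self):
        items = pd.DataFrame({"chromosome": [1], "bp": [6_000_000]})
        labelled, counts = interval_membership(items, NIL_INTROGRESSIONS)
        assert labelled.loc[0, "labels"] == ["introgression_1"]
        assert counts["introgression_1"] == 1 and counts["introgression_2"] == 0

    def test_empty_interval_set(self):
        items = pd.DataFrame({"chromosome": [1, 2], "bp": [5, 10]})
        empty = pd.DataFrame(columns=["chromosome", "start", "end", "label"])
        labelled, counts = interval_membership(items, empty)
        assert all(l == [] for l in labelled["labels"])
        assert len(counts) == 0

    def test_closed_boundary(self):
        items = pd.DataFrame({"chromosome": [1, 1, 1], "bp": [8_200_000, 8_200_001, 5_000_000]})
        labelled, _ = interval_membership(items, NIL_INTROGRESSIONS)
        assert labelled.loc[0, "labels"] == ["introgression_1"]
        assert labelled.loc[1, "labels"] == []
        assert labelled.loc[2, "labels"] == ["introgression_1"]

    def test_disjoint_counts_bounded_by_items(self):
        rng = np.random.default_rng(2)
        items = pd.DataFrame(
            {"chromosome": 1, "bp": rng.integers(0, 40_000_000, size=100)}
        )
        _, counts = interval_membership(items, NIL_INTROGRESSIONS)
        assert counts.sum() <= len(items)


class TestBinnedCounts:
    def test_one_position_per_marker(self, gmap):
        pos = pd.DataFrame({"chromosome": gmap.chromosome, "bp": gmap.bp})
        counts = binned_counts(gmap, pos)
        assert (counts == 1.0).all()

    def test_unmapped_chromosome_warns_and_ignores(self, gmap, caplog):
        pos = pd.DataFrame({"chromosome": [99], "bp": [5]})
        with caplog.at_level("WARNING"):
            counts = binned_counts(gmap, pos)
        assert counts.sum() == 0
        assert "unmapped chromosome" in caplog.text

    def test_uniform_positions_proportional_to_bin_width(self, gmap):
        rng = np.random.default_rng(6)
        L = gmap.bp[gmap.chrom_slice(1)].max()
        n = 5000
        pos = pd.DataFrame({"chromosome": 1, "bp": rng.integers(0, L, size=n)})
        counts = binned_counts(gmap, pos)
        idx = gmap.chrom_slice(1)
        mbp = gmap.bp[idx].astype(float)
        mids = (mbp[:-1] + mbp[1:]) / 2
        edges = np.r_[0.0, mids, L]
        widths = np.diff(edges)
        expected = n * widths / widths.sum()
        chi2 = ((counts.iloc[idx].to_numpy() - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, len(widths) - 1)
        assert p > 0.01

    def test_weights_summed(self, gmap):
        pos = pd.DataFrame({"chromosome": [1, 1], "bp": [0, 1]})
        counts = binned_counts(gmap, pos, weights=[0.5, 0.25])
        assert counts.iloc[0] == pytest.approx(0.75)


class TestDistributionCorrelation:
    def test_identical_vectors(self):
        res = distribution_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 5e-324 * 10

    def test_worked_example(self):
        res = distribution_correlation([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert res.r == pytest.approx(0.9)
        assert res.t_statistic == pytest.approx(3.576, abs=1e-3)
        assert res.p_value == pytest.approx(0.0374, abs=5e-4)

    def test_anticorrelated(self):
        a = np.array([1.0, 2, 3, 4])
        res = distribution_correlation(a, -a)
        assert res.r == pytest.approx(-1.0)

    def test_t_statistic_identity(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = distribution_correlation(a, b)
        assert res.t_statistic == pytest.approx(
            res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        )
        oracle = stats.pearsonr(a, b)
        assert res.r == pytest.approx(oracle.statistic)
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            distribution_correlation([1, 1, 1], [1, 2, 3])
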