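"""Mapping layer: regression oracle, thresholds, peaks, cis/trans labels."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ggxe import (
    EqtlScan,
    call_peaks,
    cis_spec,
    classify_local_distant,
    gene_locality_rollup,
    genome_scan,
    marker_regression,
    null_spec,
    permutation_threshold,
    select_cofactors,
    simulate_expression,
    simulate_null_dataset,
    trans_spec,
)
from ggxe.mapping import ScanResult


class TestMarkerRegression:
    def test_constant_trait_gives_null_result(self):
        x = np.array([1, 1, -1, -1, 1, -1], float)
        p, nl, a = marker_regression(np.ones(6), x)
        assert (p, nl, a) == (1.0, 0.0, 0.0)

    def test_worked_example_matches_pooled_ttest(self):
        y = np.array([5, 6, 5, 6, 1, 2, 1, 2], float)
        x = np.array([1, 1, 1, 1, -1, -1, -1, -1], float)
        p, nl, a = marker_regression(y, x)
        assert a == pytest.approx(2.0)
        oracle = stats.ttest_ind(y[x > 0], y[x < 0], equal_var=True)
        assert p == pytest.approx(oracle.pvalue, abs=1e-12)
        assert oracle.statistic == pytest.approx(9.798, abs=1e-3)

    def test_label_swap_negates_effect_only(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        x = np.array([1] * 10 + [-1] * 10, float)
        p1, _, a1 = marker_regression(y, x)
        p2, _, a2 = marker_regression(y, -x)
        assert a2 == pytest.approx(-a1)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_pooled_ttest_equivalence_random_instances(self):
        """Slope t-test == pooled two-sample t-test on 1000 random draws."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1 = rng.integers(2, 12)
            n2 = rng.integers(2, 12)
            y = rng.normal(size=n1 + n2)
            x = np.r_[np.ones(n1), -np.ones(n2)]
            p, _, a = marker_regression(y, x)
            oracle = stats.ttest_ind(y[:n1], y[n1:], equal_var=True)
            assert abs(p - oracle.pvalue) < 1e-10
            assert a == pytest.approx((y[:n1].mean() - y[n1:].mean()) / 2)

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            marker_regression(np.arange(6.0), np.ones(6))

    def test_zero_residual_variance_with_effect_caps(self):
        y = np.array([1, 1, 1, -1, -1, -1], float)
        x = y.copy()
        p, nl, a = marker_regression(y, x)
        assert nl == 300.0 and p == 10.0**-300.0 and a == pytest.approx(1.0)


class TestGenomeScan:
    def test_null_scan_p_uniform(self, gmap, geno160):
        expr, _ = simulate_null_dataset(geno160, gmap, 2000, seed=13)
        scan = genome_scan(expr, geno160, gmap)
        frac = (scan.p_value < 0.05).mean()
        tol = 3 * np.sqrt(0.05 * 0.95 / scan.p_value.size)
        # markers are correlated so allow a modestly wider band than iid
        assert abs(frac - 0.05) < max(3 * tol, 0.01)

    def test_neglog_matches_p(self, gmap, geno160):
        expr, _ = simulate_null_dataset(geno160, gmap, 50, seed=2)
        scan = genome_scan(expr, geno160, gmap)
        assert np.allclose(scan.neg_log10_p, -np.log10(scan.p_value), atol=1e-9)

    def test_cis_peak_at_or_near_source(self, gmap, geno160, annotation):
        """argmax lands on the source marker or a neighbour in >=95/100 reps."""
        g = annotation.index[0]
        arch = [cis_spec(g, gmap, annotation, 1.5, noise_sd=1.0)]
        src_idx = None
        hits = 0
        for rep in range(100):
            expr, truth = simulate_expression(
                geno160, gmap, arch, "GG1", ril_replicates=1, noise_seed=rep
            )
            scan = genome_scan(expr, geno160, gmap)
            if src_idx is None:
                src_idx = list(gmap.marker_ids).index(truth.spec_for(g).source_marker)
            hits += abs(int(np.argmax(scan.neg_log10_p[0])) - src_idx) <= 1
        assert hits >= 95

    def test_sign_convention_positive_beta_positive_effect(self, gmap, geno160):
        src = str(gmap.marker_ids[42])
        arch = [trans_spec("g", src, 1.0, noise_sd=1e-12)]
        expr, _ = simulate_expression(geno160, gmap, arch, "GG1", ril_replicates=1)
        scan = genome_scan(expr, geno160, gmap)
        assert scan.additive_effect[0, 42] > 0

    def test_cofactor_absorbs_own_signal(self, gmap, geno160):
        """Conditioning on the source marker kills the scan signal."""
        src = str(gmap.marker_ids[30])
        thr = 3.0
        hits = 0
        for rep in range(30):
            arch = [trans_spec("g", src, 1.5, noise_sd=1.0)]
            expr, _ = simulate_expression(
                geno160, gmap, arch, "GG1", ril_replicates=1, noise_seed=rep
            )
            scan = genome_scan(expr, geno160, gmap, cofactors={"g": [src]})
            hits += scan.neg_log10_p[0].max() < thr
        assert hits >= 28

    def test_orphan_sample_rejected(self, gmap, geno160):
        expr, _ = simulate_null_dataset(geno160, gmap, 5, seed=0)
        expr.samples.loc[:, "line"] = "ghost"
        with pytest.raises(ValueError, match="no expression sample"):
            genome_scan(expr, geno160, gmap)


class TestSelectCofactors:
    def test_disabled_returns_empty(self, gmap, geno160):
        y = np.random.default_rng(0).normal(size=160)
        assert select_cofactors(y, geno160, gmap, max_cofactors=0) == []

    def test_two_trans_effects_recovered(self, gmap, geno160):
        """Both source markers (or neighbours) selected in >=90/100 reps."""
        i1, i2 = 10, 55  # different chromosomes
        X = geno160.numeric()
        rng_master = np.random.default_rng(77)
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng([77, rep])
            y = 2.0 * X[:, i1] + 2.0 * X[:, i2] + rng.normal(0, 0.5, 160)
            sel = select_cofactors(y, geno160, gmap, max_cofactors=4, entry_p=1e-4)
            idx = [list(gmap.marker_ids).index(m) for m in sel]
            ok1 = any(abs(j - i1) <= 1 for j in idx)
            ok2 = any(abs(j - i2) <= 1 for j in idx)
            hits += ok1 and ok2
        assert hits >= 90

    def test_noise_gene_selects_nothing(self, gmap, geno160):
        hits = 0
        for rep in range(100):
            y = np.random.default_rng([5, rep]).normal(size=160)
            hits += select_cofactors(y, geno160, gmap, entry_p=1e-6) == []
        assert hits >= 99


class TestPermutationThreshold:
    def test_single_marker_threshold_is_pointwise_alpha(self, single_marker_map):
        from ggxe import simulate_ril_genotypes

        # keep only one marker: genome-wide == pointwise
        geno = simulate_ril_genotypes(single_marker_map, 100, seed=1)
        sub = type(geno)(geno.codes.iloc[:, [0]])
        frame = single_marker_map.frame.iloc[[0]]
        from ggxe.types import GeneticMap

        gm = GeneticMap(frame)
        expr, _ = simulate_null_dataset(sub, gm, 20, seed=3)
        thr = permutation_threshold(expr, sub, gm, n_permutations=10_000, seed=0)
        mc = 3 * np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(thr - 0.05) < 6 * mc

    def test_quantile_monotone_in_alpha(self, gmap, geno160):
        expr, _ = simulate_null_dataset(geno160, gmap, 50, seed=6)
        t01 = permutation_threshold(expr, geno160, gmap, 500, alpha=0.01, seed=9)
        t10 = permutation_threshold(expr, geno160, gmap, 500, alpha=0.10, seed=9)
        assert t01 <= t10

    def test_sidak_bonferroni_bracketing(self):
        """Threshold sits between Bonferroni (0.05/M_eff) and pointwise 0.05."""
        from ggxe import generate_map, simulate_ril_genotypes

        gm = generate_map(5, 35, 85.0)
        geno = simulate_ril_genotypes(gm, 120, seed=4)
        expr, _ = simulate_null_dataset(geno, gm, 100, seed=8)
        thr = permutation_threshold(expr, geno, gm, n_permutations=2000, seed=12)
        assert 0.05 / 175 < thr < 0.05

    def test_invalid_alpha_rejected(self, gmap, geno160):
        expr, _ = simulate_null_dataset(geno160, gmap, 5, seed=0)
        with pytest.raises(ValueError):
            permutation_threshold(expr, geno160, gmap, 200, alpha=1.5)


class TestCallPeaks:
    def _scan_for_profile(self, gmap, profile):
        nl = np.zeros((1, gmap.n_markers))
        nl[0, : len(profile)] = profile
        p = 10.0**-nl
        eff = np.ones_like(nl)
        return ScanResult(np.array(["g"]), gmap.marker_ids, p, nl, eff)

    def test_all_below_threshold_empty(self, gmap):
        scan = self._scan_for_profile(gmap, [0.5, 1.0, 2.0])
        assert len(call_peaks(scan, gmap, 3.62)) == 0

    def test_two_runs_two_records(self):
        from ggxe import generate_map

        gm = generate_map(1, 6, 50.0)
        profile = [0.5, 4.0, 5.2, 4.1, 0.3, 3.9]
        scan = self._scan_for_profile(gm, profile)
        peaks = call_peaks(scan, gm, 3.62)
        assert len(peaks) == 2
        assert list(peaks["peak_marker"]) == ["m1_03", "m1_06"]
        assert list(peaks["interval_start"]) == ["m1_02", "m1_06"]
        assert list(peaks["interval_end"]) == ["m1_04", "m1_06"]

    def test_whole_chromosome_run_single_record(self):
        from ggxe import generate_map

        gm = generate_map(1, 6, 50.0)
        scan = self._scan_for_profile(gm, [4.0] * 6)
        peaks = call_peaks(scan, gm, 3.62)
        assert len(peaks) == 1
        assert peaks.loc[0, "interval_start"] == "m1_01"
        assert peaks.loc[0, "interval_end"] == "m1_06"
        # tie -> leftmost peak
        assert peaks.loc[0, "peak_marker"] == "m1_01"


class TestClassifyLocalDistant:
    def _peaks(self, gmap, gene, marker):
        return pd.DataFrame(
            {
                "gene_id": [gene],
                "chromosome": [int(gmap.chromosome[gmap.index_of(marker)])],
                "peak_marker": [marker],
                "peak_neg_log10_p": [5.0],
                "additive_effect": [1.0],
                "interval_start": [marker],
                "interval_end": [marker],
                "locality": [pd.NA],
            }
        )

    def test_zero_distance_is_local(self, gmap):
        m = str(gmap.marker_ids[3])
        ann = pd.DataFrame(
            {"chromosome": [1], "bp": [gmap.bp[3]]}, index=pd.Index(["g"], name="gene_id")
        )
        out = classify_local_distant(self._peaks(gmap, "g", m), ann, gmap)
        assert out.loc[0, "locality"] == "local"

    def test_cross_chromosome_is_distant(self, gmap):
        m = str(gmap.marker_ids[0])  # chromosome 1
        ann = pd.DataFrame(
            {"chromosome": [4], "bp": [100]}, index=pd.Index(["g"], name="gene_id")
        )
        out = classify_local_distant(self._peaks(gmap, "g", m), ann, gmap)
        assert out.loc[0, "locality"] == "distant"

    @pytest.mark.parametrize(
        "offset,expected", [(2_000_000, "local"), (3_000_000, "distant")]
    )
    def test_window_boundary_inclusive(self, gmap, offset, expected):
        m = str(gmap.marker_ids[3])
        ann = pd.DataFrame(
            {"chromosome": [1], "bp": [int(gmap.bp[3]) + offset]},
            index=pd.Index(["g"], name="gene_id"),
        )
        out = classify_local_distant(
            self._peaks(gmap, "g", m), ann, gmap, window_bp=2_000_000
        )
        assert out.loc[0, "locality"] == expected

    def test_unannotated_gene_named_in_error(self, gmap):
        ann = pd.DataFrame(
            {"chromosome": [1], "bp": [0]}, index=pd.Index(["other"], name="gene_id")
        )
        with pytest.raises(ValueError, match="g"):
            classify_local_distant(
                self._peaks(gmap, "g", str(gmap.marker_ids[0])), ann, gmap
            )

    def test_rollup_categories(self):
        peaks = pd.DataFrame(
            {
                "gene_id": ["a", "a", "b", "c"],
                "locality": ["local", "distant", "local", "distant"],
            }
        )
        roll = gene_locality_rollup(peaks)
        assert roll["both"] == 1 and roll["only_local"] == 1 and roll["only_distant"] == 1


class TestModelResultsShape:
    def test_fit_and_summary(self, gmap, geno160, annotation):
        genes = list(annotation.index[:60])
        arch = [cis_spec(g, gmap, annotation, 1.5, noise_sd=1.0) for g in genes[:10]]
        arch += [null_spec(g) for g in genes[10:]]
        expr, _ = simulate_expression(
            geno160, gmap, arch, "GG2", ril_replicates=1, noise_seed=5,
            annotation=annotation,
        )
        res = EqtlScan(expr, geno160, gmap, "GG2").fit()
        res.permutation_threshold(n_permutations=500, seed=2)
        peaks = res.call_peaks()
        text = res.summary()
        assert "genes with eQTL" in text and "permutation p thr" in text
        assert peaks["peak_neg_log10_p"].min() >= res.thresholds.final_neg_log10_threshold
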