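"""Region methylation summaries, beta-binomial differential test, promoters, metagene."""

import numpy as np
import pytest

from tmrcall.annotation import TranscriptModel
from tmrcall.intervals import GenomicInterval
from tmrcall.methylome import MethylomeMatrix
from tmrcall.regions import (
    PromoterDefinition,
    beta_binomial_diff_meth,
    classify_calls,
    metagene_density,
    promoter_definition_analysis,
    promoter_interval,
    region_expression_correlation,
    region_mean_methylation,
)


def _matrix(meth, total, positions=None, samples=None):
    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    n, s = meth.shape
    positions = np.arange(n) * 100 + 1000 if positions is None else np.asarray(positions)
    samples = [f"s{j}" for j in range(s)] if samples is None else samples
    beta = np.full(meth.shape, np.nan)
    np.divide(meth, total, out=beta, where=total > 0)
    return MethylomeMatrix(
        np.array(["chr1"] * n, dtype=object), positions.astype(np.int64), samples, meth, total, beta
    )


class TestRegionMean:
    def test_mean_of_overlapping_betas(self):
        m = _matrix([[2], [4]], [[10], [10]])  # betas 0.2, 0.4
        assert region_mean_methylation(GenomicInterval("chr1", 900, 1200), m, "s0") == pytest.approx(0.3)

    def test_no_cpgs_is_missing(self):
        m = _matrix([[2]], [[10]])
        assert np.isnan(region_mean_methylation(GenomicInterval("chr2", 0, 100), m, "s0"))

    def test_masked_cpg_excluded_from_mean(self):
        m = _matrix([[2], [4], [9]], [[10], [10], [10]])
        m.beta[1, 0] = np.nan  # mask middle CpG
        got = region_mean_methylation(GenomicInterval("chr1", 900, 1300), m, "s0")
        assert got == pytest.approx((0.2 + 0.9) / 2)

    def test_disjoint_concatenation_is_count_weighted_mean(self):
        rng = np.random.default_rng(0)
        total = np.full((6, 1), 50)
        meth = rng.integers(0, 50, size=(6, 1))
        m = _matrix(meth, total)
        left = region_mean_methylation(GenomicInterval("chr1", 900, 1250), m, "s0")  # 3 CpGs
        right = region_mean_methylation(GenomicInterval("chr1", 1250, 1600), m, "s0")  # 3 CpGs
        both = region_mean_methylation(GenomicInterval("chr1", 900, 1600), m, "s0")
        assert both == pytest.approx((left + right) / 2)


class TestRegionExpressionCorrelation:
    def test_single_cpg_region_equals_site_correlation(self):
        rng = np.random.default_rng(1)
        n = 40
        total = np.full((1, n), 50)
        meth = rng.integers(0, 50, size=(1, n))
        m = _matrix(meth, total)
        y = rng.standard_normal(n)
        rho, p, used = region_expression_correlation(
            GenomicInterval("chr1", 900, 1100), y, m, min_samples=30
        )
        from tmrcall.correlation import spearman

        site_rho, _ = spearman(m.beta[0], y)
        assert rho == pytest.approx(site_rho, abs=1e-12) and used == n

    def test_constant_region_means_missing(self):
        m = _matrix([[25] * 35], [[50] * 35])
        rho, p, _ = region_expression_correlation(
            GenomicInterval("chr1", 900, 1100), np.arange(35.0), m, min_samples=30
        )
        assert np.isnan(rho) and np.isnan(p)


class TestBetaBinomial:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(2)
        total = rng.integers(20, 60, size=(4, 6))
        meth = rng.binomial(total, 0.5)
        both = np.hstack([total, total])
        mboth = np.hstack([meth, meth])
        m = _matrix(mboth, both, samples=[f"s{j}" for j in range(12)])
        res = beta_binomial_diff_meth(
            GenomicInterval("chr1", 900, 2000), m,
            [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)],
        )
        assert abs(res.meth_diff) < 0.02
        assert res.p > 0.5

    def test_extreme_separation_is_overwhelming(self):
        total = np.full((1, 10), 50)
        meth = np.array([[0] * 5 + [50] * 5])
        m = _matrix(meth, total, samples=[f"s{j}" for j in range(10)])
        res = beta_binomial_diff_meth(
            GenomicInterval("chr1", 900, 1100), m,
            [f"s{j}" for j in range(5, 10)], [f"s{j}" for j in range(5)],
        )
        assert res.p < 1e-6
        assert res.meth_diff == pytest.approx(1.0, abs=0.02)

    def test_group_swap_flips_sign_and_keeps_p(self):
        rng = np.random.default_rng(3)
        total = rng.integers(20, 60, size=(3, 12))
        meth = rng.binomial(total, np.linspace(0.2, 0.7, 12))
        m = _matrix(meth, total, samples=[f"s{j}" for j in range(12)])
        region = GenomicInterval("chr1", 900, 2000)
        ga = [f"s{j}" for j in range(6)]
        gb = [f"s{j}" for j in range(6, 12)]
        ab = beta_binomial_diff_meth(region, m, ga, gb)
        ba = beta_binomial_diff_meth(region, m, gb, ga)
        assert ab.meth_diff == pytest.approx(-ba.meth_diff, abs=1e-4)
        assert ab.p == pytest.approx(ba.p, rel=1e-3)

    def test_too_few_covered_samples_is_none(self):
        m = _matrix([[5, 0, 5, 5]], [[10, 0, 10, 10]])
        res = beta_binomial_diff_meth(
            GenomicInterval("chr1", 900, 1100), m, ["s0", "s1"], ["s2", "s3"]
        )
        assert res is None  # group A has a single covered sample

    def test_classify_sets_bh_and_calls(self):
        from tmrcall.regions import RegionMethylationResult

        results = []
        for p, diff in [(0.001, 0.3), (0.5, 0.1), (0.002, -0.2)]:
            results.append(
                RegionMethylationResult(
                    region=GenomicInterval("chr1", 0, 10),
                    group_means=(0.5 + diff / 2, 0.5 - diff / 2),
                    meth_diff=diff,
                    p=p,
                )
            )
        classify_calls(results, alpha=0.05)
        assert [r.call for r in results] == ["hyper", "ns", "hypo"]
        assert all(r.q >= r.p for r in results)


class TestPromoterAnalysis:
    def _model(self, strand="+"):
        body = (
            GenomicInterval("chr1", 5000, 9000, strand=strand)
            if strand == "+"
            else GenomicInterval("chr1", 1000, 5001, strand=strand)
        )
        return TranscriptModel("T", "G", body)  # TSS at 5000 either way

    def test_promoter_interval_strand_aware(self):
        d = PromoterDefinition("X", upstream_bp=200, downstream_bp=100)
        plus = promoter_interval(self._model("+"), d)
        minus = promoter_interval(self._model("-"), d)
        assert (plus.start, plus.end) == (4800, 5100)
        assert (minus.start, minus.end) == (4901, 5201)

    def _cohort_with_opposed_flanks(self):
        """Upstream CpGs hypo in group A, downstream CpGs hyper in group A."""
        positions = np.array([4940, 4960, 4980, 5020, 5040, 5060])
        n_per = 5
        samples = [f"a{j}" for j in range(n_per)] + [f"b{j}" for j in range(n_per)]
        total = np.full((6, 2 * n_per), 60, dtype=np.int64)
        meth = np.zeros_like(total)
        meth[:3, :n_per] = 6   # upstream, group A: 10%
        meth[:3, n_per:] = 54  # upstream, group B: 90%
        meth[3:, :n_per] = 54  # downstream, group A: 90%
        meth[3:, n_per:] = 6   # downstream, group B: 10%
        m = _matrix(meth, total, positions=positions, samples=samples)
        return m, samples[:n_per], samples[n_per:]

    def test_opposed_flanks_are_contradictory_between_definitions(self):
        m, ga, gb = self._cohort_with_opposed_flanks()
        model = TranscriptModel("T", "G", GenomicInterval("chr1", 5000, 9000, strand="+"))
        up_only = PromoterDefinition("U", upstream_bp=80, downstream_bp=0)
        down_only = PromoterDefinition("D", upstream_bp=0, downstream_bp=80)
        res = promoter_definition_analysis([up_only, down_only], [model], m, ga, gb)
        assert res["n_contradictory"] == 1
        assert res["contradictory"] == ["T"]

    def test_identical_definitions_never_contradict(self):
        m, ga, gb = self._cohort_with_opposed_flanks()
        model = TranscriptModel("T", "G", GenomicInterval("chr1", 5000, 9000, strand="+"))
        d1 = PromoterDefinition("A", 80, 0)
        d2 = PromoterDefinition("B", 80, 0)
        res = promoter_definition_analysis([d1, d2], [model], m, ga, gb)
        assert res["n_contradictory"] == 0
        assert res["intersection"].loc["A", "B"] == res["intersection"].loc["A", "A"]

    def test_exclusive_counts_match_recomputation(self):
        m, ga, gb = self._cohort_with_opposed_flanks()
        model = TranscriptModel("T", "G", GenomicInterval("chr1", 5000, 9000, strand="+"))
        defs = [PromoterDefinition("U", 80, 0), PromoterDefinition("D", 0, 80)]
        res = promoter_definition_analysis(defs, [model], m, ga, gb)
        sig = res["calls"].isin(["hyper", "hypo"])
        for lab in ("U", "D"):
            other = [l for l in ("U", "D") if l != lab][0]
            expected = int((sig[lab] & ~sig[other]).sum())
            assert res["exclusive"][lab] == expected


class TestMetagene:
    def _models(self, strand="+"):
        return [TranscriptModel("T", "G", GenomicInterval("chr1", 10_000, 20_000, strand=strand))]

    def test_midpoint_at_tss_lands_in_first_body_bin(self):
        feats = [GenomicInterval("chr1", 9_999, 10_002)]  # midpoint 10000 = TSS
        prof = metagene_density(feats, self._models("+"))
        assert prof.body[0] == 1.0 and prof.n_features_assigned == 1

    def test_forty_percent_on_minus_strand_maps_to_bin_41(self):
        models = self._models("-")  # TSS at 19999, length 10000
        # u = 0.4 * L  ->  midpoint = 19999 - 4000
        mid = 19_999 - 4_000
        feats = [GenomicInterval("chr1", mid - 1, mid + 2)]
        prof = metagene_density(feats, models)
        assert prof.body[40] == 1.0  # bin 41 counting from the TSS-proximal end

    def test_flank_bins_extend_from_tss_and_tes(self):
        feats = [
            GenomicInterval("chr1", 9_400, 9_402),  # 599 bp upstream of TSS
            GenomicInterval("chr1", 20_300, 20_302),  # ~300 bp past TES
        ]
        prof = metagene_density(feats, self._models("+"))
        assert prof.upstream[-2] == 1.0  # second-to-last 500bp bin before TSS
        assert prof.downstream[0] == 1.0

    def test_uniform_features_fill_body_uniformly(self):
        rng = np.random.default_rng(5)
        feats = [
            GenomicInterval("chr1", int(p), int(p) + 2)
            for p in rng.integers(10_000, 19_998, size=5000)
        ]
        prof = metagene_density(feats, self._models("+"))
        counts = prof.body * 1  # one transcript -> densities are counts
        expected = 5000 / 100
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))

    def test_counts_conserved(self):
        rng = np.random.default_rng(6)
        feats = [
            GenomicInterval("chr1", int(p), int(p) + 2)
            for p in rng.integers(4_000, 26_000, size=800)
        ]
        models = self._models("+")
        prof = metagene_density(feats, models)
        assert prof.densities.sum() * len(models) == pytest.approx(prof.n_features_assigned)
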