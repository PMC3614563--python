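import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trioexome import (
    SegmentationParams,
    call_cnvs,
    exon_stats,
    fisher_combined,
    gh_pvalue,
    log_ratio_track,
    make_null_cohort,
    rpkm,
    segment,
    smooth_and_merge,
)
from trioexome.cnv_caller import RawSegment, segment_significance
from trioexome.errors import ValidationError

FAST = SegmentationParams(n_permutations=200, alpha=0.01, min_exons=20, seed=0)


def make_track(values, chrom="chr1"):
    n = len(values)
    return pd.DataFrame({
        "chrom": [chrom] * n,
        "start": np.arange(n) * 1000,
        "end": np.arange(n) * 1000 + 200,
        "exon_id": [f"{chrom}_e{i}" for i in range(n)],
        "log_ratio": values,
        "masked": [False] * n,
    })


class TestRpkm:
    def test_reference_value(self):
        assert rpkm(1000, 1000, 10**8) == 10.0

    def test_zero_count(self):
        assert rpkm(0, 500, 10**7) == 0.0

    def test_linearity(self):
        base = rpkm(100, 500, 10**7)
        assert rpkm(200, 500, 10**7) == pytest.approx(2 * base)
        assert rpkm(100, 500, 2 * 10**7) == pytest.approx(base / 2)

    def test_zero_length_or_total_rejected(self):
        with pytest.raises(ValidationError):
            rpkm(10, 0, 10**7)
        with pytest.raises(ValidationError):
            rpkm(10, 100, 0)


class TestGearyHinkley:
    def test_null_ratio_gives_t_zero_p_one(self):
        t, p = gh_pvalue(100, 100, 10**7, 10**7)
        assert t == 0.0 and p == 1.0
        # scaled libraries: tumor count = s * blood count is also null
        t, p = gh_pvalue(200, 100, 2 * 10**7, 10**7)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_reference_value_70_of_100(self):
        t, p = gh_pvalue(70, 100, 10**6, 10**6)
        assert t == pytest.approx(-30 / np.sqrt(149), abs=1e-12)
        assert p == pytest.approx(0.0140, abs=1e-4)

    def test_sign_flip_symmetry(self):
        # deviation R and 1/R give opposite t, identical p
        for ratio in (0.5, 0.7, 0.9):
            t1, p1 = gh_pvalue(100 * ratio, 100, 10**6, 10**6)
            t2, p2 = gh_pvalue(100 / ratio, 100, 10**6, 10**6)
            assert t2 == pytest.approx(-t1, abs=1e-6)
            assert p2 == pytest.approx(p1, abs=1e-6)

    def test_t_magnitude_increases_with_deviation(self):
        devs = [100 + d for d in (0, 5, 10, 20, 40)]
        ts = [abs(gh_pvalue(n, 100, 10**6, 10**6)[0]) for n in devs]
        assert ts == sorted(ts)
        ts_down = [abs(gh_pvalue(100 - d, 100, 10**6, 10**6)[0]) for d in (0, 5, 10, 20)]
        assert ts_down == sorted(ts_down)

    def test_tail_probability_matches_ratio_of_normals_simulation(self):
        # P(X/Y <= 0.7) for X, Y ~ Normal(100, 100) should equal Phi(t(0.7))
        rng = np.random.default_rng(123)
        x = rng.normal(100, 10, size=200_000)
        y = rng.normal(100, 10, size=200_000)
        empirical = np.mean(x / y <= 0.7)
        t, _ = gh_pvalue(70, 100, 10**6, 10**6)
        assert empirical == pytest.approx(stats.norm.cdf(t), abs=0.002)

    def test_null_cohort_calibration(self):
        cov = make_null_cohort(4000, mean_depth=150, seed=2)
        df = exon_stats(cov, "blood", "tumor")
        p = df.loc[~df["masked"], "p"]
        for alpha in (0.01, 0.05):
            frac = (p < alpha).mean()
            band = 3 * np.sqrt(alpha * (1 - alpha) / len(p))
            assert abs(frac - alpha) < band + 0.003


class TestLogRatioTrack:
    def test_identical_columns_give_zero(self):
        cov = make_null_cohort(50, seed=0)
        cov.counts[:, 1] = cov.counts[:, 0]
        track = log_ratio_track(cov, "blood", "tumor")
        ok = ~track["masked"]
        assert np.allclose(track.loc[ok, "log_ratio"], 0.0)

    def test_halved_tumor_gives_minus_one(self):
        cov = make_null_cohort(50, mean_depth=200, seed=1)
        cov.counts[:, 1] = cov.counts[:, 0] // 2
        cov.counts[:, 0] = 2 * cov.counts[:, 1]  # make the halving exact
        track = log_ratio_track(cov, "blood", "tumor")
        ok = ~track["masked"] & (track["count_tumor"] > 0)
        assert np.allclose(track.loc[ok, "log_ratio"], -1.0)

    def test_low_blood_exons_masked_not_zero_filled(self):
        cov = make_null_cohort(50, seed=3)
        cov.counts[7, 0] = 4
        track = log_ratio_track(cov, "blood", "tumor", mask_min_blood=10)
        assert bool(track["masked"].iloc[7])


class TestSegmentation:
    def test_flat_track_single_segment(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.normal(0, 0.1, 500))
        segs = segment(track, FAST)
        assert len(segs) == 1
        assert segs[0].n_exons == 500

    def test_step_track_two_segments_with_accurate_boundary(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.1, 200), rng.normal(-0.5, 0.1, 200)])
        segs = segment(make_track(x), FAST)
        assert len(segs) == 2
        assert segs[0].n_exons == pytest.approx(200, abs=3)
        assert segs[0].mean_log_ratio == pytest.approx(0.0, abs=0.05)
        assert segs[1].mean_log_ratio == pytest.approx(-0.5, abs=0.05)

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.1, 150), rng.normal(0.6, 0.1, 80),
                            rng.normal(0, 0.1, 150)])
        track = make_track(x)
        track.loc[10, "masked"] = True
        segs = segment(track, FAST)
        rows = np.concatenate([s.rows for s in segs])
        expected = np.setdiff1d(np.arange(len(x)), [10])
        np.testing.assert_array_equal(np.sort(rows), expected)
        assert len(rows) == len(set(rows))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.15, 120), rng.normal(-0.4, 0.15, 120)])
        a = segment(make_track(x), FAST)
        b = segment(make_track(x), FAST)
        assert [(s.start_bp, s.end_bp) for s in a] == [(s.start_bp, s.end_bp) for s in b]


def raw(chrom, mean, n, first=0):
    rows = np.arange(first, first + n)
    return RawSegment(chrom=chrom, start_bp=int(rows[0]) * 1000,
                      end_bp=int(rows[-1]) * 1000 + 200, n_exons=n,
                      mean_log_ratio=mean, rows=rows)


class TestSmoothAndMerge:
    PARAMS = SegmentationParams(min_exons=100)

    def test_similar_negative_neighbors_merge_with_weighted_mean(self):
        segs = [raw("chr1", -0.50, 120), raw("chr1", -0.55, 60, first=120)]
        merged = smooth_and_merge(segs, self.PARAMS)
        assert len(merged) == 1
        assert merged[0].n_exons == 180
        expected = (-0.50 * 120 - 0.55 * 60) / 180
        assert merged[0].mean_log_ratio == pytest.approx(expected)

    def test_small_segment_dropped(self):
        assert smooth_and_merge([raw("chr1", -0.5, 50)], self.PARAMS) == []

    def test_opposite_signs_never_merge(self):
        segs = [raw("chr1", -0.5, 150), raw("chr1", 0.5, 150, first=150)]
        merged = smooth_and_merge(segs, self.PARAMS)
        assert len(merged) == 2

    def test_mean_gap_above_tolerance_blocks_merge(self):
        segs = [raw("chr1", -0.2, 150), raw("chr1", -0.5, 150, first=150)]
        merged = smooth_and_merge(segs, SegmentationParams(min_exons=100, merge_gap_tolerance=0.2))
        assert len(merged) == 2

    def test_weak_segment_below_call_threshold_dropped(self):
        assert smooth_and_merge([raw("chr1", 0.05, 400)], self.PARAMS) == []

    def test_different_chromosomes_never_merge(self):
        segs = [raw("chr1", -0.5, 150), raw("chr2", -0.5, 150)]
        assert len(smooth_and_merge(segs, self.PARAMS)) == 2


class TestFisher:
    def test_single_p_is_identity(self):
        assert fisher_combined([0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_all_ones_combine_to_one(self):
        assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_reference_triple(self):
        # X = -2 (ln .1 + ln .2 + ln .3) = 10.232, chi2 tail with 6 df
        assert fisher_combined([0.1, 0.2, 0.3]) == pytest.approx(0.1152, abs=1e-4)

    def test_statistic_is_exact_brute_force_sum(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, size=40)
        x = -2.0 * np.sum(np.log(p))
        assert fisher_combined(p) == stats.chi2.sf(x, 2 * len(p))

    def test_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-4, 1, size=25)
        _, expected = stats.combine_pvalues(p, method="fisher")
        assert fisher_combined(p) == pytest.approx(expected, rel=1e-12)

    def test_underflow_floors_at_tiny_positive(self):
        assert fisher_combined([1e-300] * 10) == 1e-300

    def test_zero_p_rejected(self):
        with pytest.raises(ValidationError):
            fisher_combined([0.0, 0.5])


class TestCallCnvs:
    def test_null_cohort_yields_no_calls(self):
        cov = make_null_cohort(3000, seed=9)
        table = call_cnvs(cov, "blood", "tumor", SegmentationParams(seed=1))
        assert len(table) == 0

    def test_planted_lesions_recovered_with_correct_signs(self, small_cohort):
        _, cov, _, truth = small_cohort
        table = call_cnvs(cov, "blood", "OMN", SegmentationParams(seed=4))
        assert len(table) == 2
        by_chrom = {r.chrom: r for r in table.df.itertuples(index=False)}
        assert by_chrom["chr1"].call == "del"
        assert by_chrom["chr2"].call == "amp"
        for _, t in truth.segments.iterrows():
            call = by_chrom[t.chrom]
            overlap_start = max(call.start, t.start_bp)
            overlap_end = min(call.end, t.end_bp)
            truth_exons = t.last_exon - t.first_exon
            overlap_exons = max(0, (overlap_end - overlap_start)) / 1000
            assert overlap_exons / truth_exons >= 0.95

    def test_combined_p_extreme_for_large_lesions(self, small_cohort):
        _, cov, _, _ = small_cohort
        table = call_cnvs(cov, "blood", "OMN", SegmentationParams(seed=4))
        assert (table.df["combined_p"] < 1e-50).all()

    def test_purity_magnifies_log_ratios(self, small_cohort):
        _, cov, _, _ = small_cohort
        low = call_cnvs(cov, "blood", "OV", SegmentationParams(seed=2))
        high = call_cnvs(cov, "blood", "OMN", SegmentationParams(seed=2))
        for chrom in ("chr1", "chr2"):
            m_low = low.df.loc[low.df["chrom"] == chrom, "mean_log_ratio"].iloc[0]
            m_high = high.df.loc[high.df["chrom"] == chrom, "mean_log_ratio"].iloc[0]
            assert abs(m_high) > abs(m_low)

    def test_segment_significance_requires_unmasked_p(self):
        track = make_track([0.1, 0.2])
        track["p"] = [np.nan, np.nan]
        seg = raw("chr1", 0.15, 2)
        with pytest.raises(ValidationError):
            segment_significance(seg, track)
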