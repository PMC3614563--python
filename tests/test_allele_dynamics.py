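import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trioexome import (
    FrequencySeries,
    SangerTrace,
    allele_frequency,
    build_frequency_series,
    concordance,
    estimate_purity,
    load_validation_cohort,
    proportion_to_frequency,
    select_rising_variants,
)
from trioexome.allele_dynamics import concordance_by_sample
from trioexome.errors import ConfigError, InsufficientDataError, ValidationError


def series(key, exome, sanger=None, samples=("OV", "OMN", "REC")):
    return FrequencySeries(
        key=key, samples=samples,
        af_exome=dict(zip(samples, exome)),
        af_sanger=dict(zip(samples, sanger)) if sanger else {},
    )


class TestAlleleFrequency:
    @pytest.mark.parametrize("alt,depth,expected", [(57, 100, 0.57), (0, 50, 0.0), (7, 7, 1.0)])
    def test_ratio(self, alt, depth, expected):
        assert allele_frequency(alt, depth) == expected

    def test_zero_depth_is_missing_not_error(self):
        assert math.isnan(allele_frequency(0, 0))


class TestSangerConversion:
    @pytest.mark.parametrize("ref,alt,expected", [
        (100, 100, 0.5),   # equal peaks
        (100, 300, 0.75),  # proportion 3
        (100, 0, 0.0),
        (0, 100, 1.0),
    ])
    def test_known_points(self, ref, alt, expected):
        assert proportion_to_frequency(SangerTrace(ref, alt)) == pytest.approx(expected)

    def test_negative_heights_rejected(self):
        with pytest.raises(ValidationError):
            SangerTrace(-1, 10)

    def test_round_trip_exact_on_grid(self):
        # frequency -> proportion f/(1-f) -> frequency is the identity
        for f in np.linspace(0.001, 0.999, 999):
            r = f / (1 - f)
            back = proportion_to_frequency(SangerTrace(1.0, r))
            assert abs(back - f) <= 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_strictly_increasing_in_proportion(self, r1, r2):
        f1 = proportion_to_frequency(SangerTrace(1.0, r1))
        f2 = proportion_to_frequency(SangerTrace(1.0, r2))
        assert (r1 < r2) == (f1 < f2) or r1 == r2
        assert 0 < f1 < 1


class TestRisingSelection:
    def test_strong_riser_selected_under_both_modes(self):
        s = series("TP53", (0.21, 0.47, 0.68))
        for mode in ("relative", "absolute"):
            assert select_rising_variants([s], mode=mode) == [s]

    def test_small_relative_rise_selected_under_relative_only(self):
        s = series("PLXNB3", (0.17, 0.21, 0.19))  # +23.5% relative, +0.04 absolute
        assert select_rising_variants([s], mode="relative") == [s]
        assert select_rising_variants([s], mode="absolute") == []

    def test_flat_series_not_selected(self):
        assert select_rising_variants([series("flat", (0.30, 0.30, 0.30))]) == []

    def test_missing_later_samples_ignored(self):
        s = FrequencySeries("x", ("OV", "OMN", "REC"), af_exome={"OV": 0.2, "REC": 0.5})
        assert select_rising_variants([s]) == [s]
        no_later = FrequencySeries("y", ("OV", "OMN", "REC"), af_exome={"OV": 0.2})
        assert select_rising_variants([no_later]) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            select_rising_variants([], threshold=-0.1)


def brute_force_spearman(x, y):
    """Spearman rho straight from the rank definition with average ranks."""
    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestConcordance:
    def test_validation_cohort_matches_published_correlation(self):
        result = concordance(load_validation_cohort())
        assert result.rho == pytest.approx(0.78, abs=0.01)
        assert result.n_pairs == 66
        assert result.p_value < 1e-12

    def test_identical_pairs_give_rho_one(self):
        ss = [series(f"v{i}", (a, a + 0.1, a + 0.2), (a, a + 0.1, a + 0.2))
              for i, a in enumerate((0.1, 0.3, 0.5))]
        assert concordance(ss).rho == pytest.approx(1.0)

    def test_matches_brute_force_rank_definition(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.uniform(0, 1, 10), 2)  # rounding forces ties
        y = np.round(rng.uniform(0, 1, 10), 2)
        ss = [series(f"v{i}", (x[i],) , (y[i],), samples=("OV",)) for i in range(10)]
        got = concordance(ss, samples=("OV",))
        assert got.rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert got.n_pairs == 10

    def test_invariant_under_monotone_transform_of_both_members(self):
        ss = load_validation_cohort()
        base = concordance(ss).rho
        transformed = []
        for fs in ss:
            transformed.append(FrequencySeries(
                fs.key, fs.samples,
                af_exome={s: v**3 for s, v in fs.af_exome.items()},
                af_sanger={s: v**3 for s, v in fs.af_sanger.items()},
            ))
        assert concordance(transformed).rho == pytest.approx(base, abs=1e-12)

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            concordance([series("v", (0.1, 0.2, 0.3), (0.1, 0.2, 0.3))][:0] or
                        [FrequencySeries("v", ("OV",), {"OV": 0.1}, {"OV": 0.2})])

    def test_stratified_report_covers_each_sample(self):
        per = concordance_by_sample(load_validation_cohort())
        assert set(per) == {"OV", "OMN", "REC"}
        assert all(r.n_pairs == 22 for r in per.values())


class TestPurityEstimate:
    def test_half_afs_mean_pure_tumor(self):
        assert estimate_purity([0.5] * 5, "OMN").pi_hat == 1.0

    def test_quarter_afs_mean_half_purity(self):
        assert estimate_purity([0.25] * 5, "OV").pi_hat == 0.5

    def test_empty_input_gives_no_estimate(self):
        assert estimate_purity([], "OV") is None
        assert estimate_purity([float("nan")], "OV") is None

    def test_recovers_purity_from_binomial_afs(self):
        rng = np.random.default_rng(11)
        pi, depth = 0.6, 150
        afs = rng.binomial(depth, pi / 2, size=20) / depth
        est = estimate_purity(afs.tolist(), "OMN")
        assert est.pi_hat == pytest.approx(pi, abs=0.05)
        assert est.n_variants == 20
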