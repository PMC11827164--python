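import numpy as np
import pandas as pd
import pytest

from coexnet.containers import CountMatrix, SampleSheet
from coexnet.normalize import (ClassificationThresholds, HousekeepingSet,
                               category_sum, classify_expression,
                               log10_heatmap, median_of_ratios_size_factors,
                               normalize_and_average, proportion_percent,
                               round_half_away)


class TestSizeFactors:
    def test_doubled_library_gives_factors_in_ratio_one_to_two(self):
        # hand arithmetic: for counts (2, 4) the reference is sqrt(8), so the
        # ratios are (0.7071..., 1.4142...); medians keep the 1:2 ratio
        frame = pd.DataFrame({"s1": [2, 10, 100], "s2": [4, 20, 200]},
                             index=["g1", "g2", "g3"])
        factors = median_of_ratios_size_factors(CountMatrix(frame, stage="raw"))
        assert factors["s2"] / factors["s1"] == pytest.approx(2.0, abs=1e-12)
        assert factors["s1"] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_identical_samples_give_equal_factors(self):
        frame = pd.DataFrame({"s1": [5, 9], "s2": [5, 9], "s3": [5, 9]},
                             index=["g1", "g2"])
        factors = median_of_ratios_size_factors(CountMatrix(frame, stage="raw"))
        assert factors.factors.nunique() == 1

    def test_single_sample_gets_factor_one(self):
        frame = pd.DataFrame({"s1": [5, 9, 13]}, index=["g1", "g2", "g3"])
        factors = median_of_ratios_size_factors(CountMatrix(frame, stage="raw"))
        assert factors["s1"] == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_gene_changes_nothing(self, tiny_raw_matrix):
        base = median_of_ratios_size_factors(tiny_raw_matrix)
        widened = pd.concat([
            tiny_raw_matrix.values,
            pd.DataFrame({"s1": [0], "s2": [0]}, index=["silent"]),
        ])
        with_zero = median_of_ratios_size_factors(CountMatrix(widened, stage="raw"))
        pd.testing.assert_series_equal(base.factors, with_zero.factors)

    def test_no_all_positive_gene_is_a_hard_error(self):
        frame = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="positive counts in every sample"):
            median_of_ratios_size_factors(CountMatrix(frame, stage="raw"))

    def test_scaling_one_sample_scales_factor_ratio_by_c(self):
        # median-of-ratios identifies factors only up to one global constant,
        # so the equivariance is exact on factor ratios and on normalized
        # values up to a single common scale
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.integers(10, 1000, size=(50, 4)),
                             index=[f"g{i}" for i in range(50)],
                             columns=list("abcd"))
        c = 3.0
        scaled = frame.copy()
        scaled["b"] = (scaled["b"] * c).astype(int)
        f0 = median_of_ratios_size_factors(CountMatrix(frame, stage="raw")).factors
        f1 = median_of_ratios_size_factors(CountMatrix(scaled, stage="raw")).factors
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(c, rel=1e-9)
        norm0 = frame.to_numpy() / f0.to_numpy()
        norm1 = scaled.to_numpy() / f1.to_numpy()
        ratio = norm1 / norm0
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-9)


class TestNormalizeAndAverage:
    def test_replicates_average_and_round_half_away(self, duplicate_sheet):
        frame = pd.DataFrame({"s1": [2, 3], "s2": [4, 4]}, index=["g1", "g2"])
        matrix = CountMatrix(frame, stage="raw")
        # unit factors so the arithmetic is transparent
        from coexnet.normalize import SizeFactors
        unit = SizeFactors(pd.Series([1.0, 1.0], index=["s1", "s2"]))
        avg = normalize_and_average(matrix, duplicate_sheet, unit)
        assert avg.stage == "averaged"
        assert avg.values.loc["g1", "c1"] == 3    # (2+4)/2
        assert avg.values.loc["g2", "c1"] == 4    # 3.5 rounds away from zero

    def test_single_sample_condition_passes_through(self):
        frame = pd.DataFrame({"s1": [10, 20], "s2": [12, 22], "ext": [7, 9]},
                             index=["g1", "g2"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["s1", "s2", "ext"],
            "condition": ["c1", "c1", "retrieved"],
            "replicate": [1, 2, 1],
        }))
        from coexnet.normalize import SizeFactors
        unit = SizeFactors(pd.Series(1.0, index=["s1", "s2", "ext"]))
        avg = normalize_and_average(CountMatrix(frame, stage="raw"), sheet, unit)
        assert list(avg.values.columns) == ["c1", "retrieved"]
        assert avg.values.loc["g1", "retrieved"] == 7

    def test_sheet_sample_missing_from_matrix_errors(self, tiny_raw_matrix):
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["s1", "s2", "ghost"],
            "condition": ["c1", "c1", "c2"],
            "replicate": [1, 2, 1],
        }))
        with pytest.raises(ValueError, match="ghost"):
            normalize_and_average(tiny_raw_matrix, sheet)


def test_round_half_away_matches_spreadsheet_convention():
    assert round_half_away(3.5) == 4
    assert round_half_away(2.5) == 3
    assert round_half_away(-3.5) == -4
    assert round_half_away(2.4) == 2


class TestClassifyExpression:
    def _matrix(self, ratios):
        # housekeeping mean is 100 in the single condition
        rows = {"hk1": [100.0], "hk2": [100.0], "hk3": [100.0]}
        rows.update({f"g{i}": [100.0 * r] for i, r in enumerate(ratios)})
        return CountMatrix(pd.DataFrame(rows, index=None).T.set_axis(["c1"], axis=1),
                           stage="averaged")

    def test_toy_ratios_map_to_expected_tiers(self):
        matrix = self._matrix([0.6, 0.2, 0.02, 0.005, 0.0])
        result = classify_expression(matrix, HousekeepingSet(("hk1", "hk2", "hk3")))
        tiers = result.frame.loc[[f"g{i}" for i in range(5)], "tier"].tolist()
        assert tiers == ["high", "moderate", "detectable", "below", "below"]

    def test_gene_matching_housekeeping_mean_is_high(self):
        matrix = self._matrix([1.0])
        result = classify_expression(matrix, HousekeepingSet(("hk1", "hk2", "hk3")))
        assert result.frame.loc["g0", "tier"] == "high"
        assert result.frame.loc["g0", "peak_ratio"] == pytest.approx(1.0)

    def test_strict_thresholds_exclude_exact_boundary(self):
        matrix = self._matrix([0.5])
        strict = classify_expression(matrix, HousekeepingSet(("hk1", "hk2", "hk3")))
        assert strict.frame.loc["g0", "tier"] == "moderate"
        inclusive = classify_expression(
            matrix, HousekeepingSet(("hk1", "hk2", "hk3")),
            ClassificationThresholds(strict=False))
        assert inclusive.frame.loc["g0", "tier"] == "high"

    def test_silent_housekeeping_reference_is_a_hard_error(self):
        frame = pd.DataFrame({"c1": [0.0, 0.0, 0.0, 5.0]},
                             index=["hk1", "hk2", "hk3", "g0"])
        with pytest.raises(ValueError, match="housekeeping"):
            classify_expression(CountMatrix(frame, stage="averaged"),
                                HousekeepingSet(("hk1", "hk2", "hk3")))

    def test_nested_counts_accumulate_tiers(self):
        matrix = self._matrix([0.6, 0.2, 0.02, 0.005])
        result = classify_expression(matrix, HousekeepingSet(("hk1", "hk2", "hk3")))
        nested = result.tier_counts(nested=True)
        # housekeeping genes themselves classify as high (ratio 1.0)
        assert nested["high"] == 4 and nested["moderate"] == 5
        assert nested["detectable"] == 6


class TestLog10Heatmap:
    def test_log10_with_zero_rule(self):
        frame = pd.DataFrame({"c1": [1e10, 0.0, 1000.0, 0.5]},
                             index=["g1", "g2", "g3", "g4"])
        table = log10_heatmap(CountMatrix(frame, stage="averaged"))
        assert table.values.loc["g1", "c1"] == 10.0
        assert table.values.loc["g2", "c1"] == 0.0
        assert table.values.loc["g3", "c1"] == 3.0
        assert table.values.loc["g4", "c1"] == 0.0  # below 1 maps to 0, not -inf

    def test_values_above_ceiling_are_not_clipped(self):
        frame = pd.DataFrame({"c1": [1e12]}, index=["g1"])
        table = log10_heatmap(CountMatrix(frame, stage="averaged"), floor=4.5)
        assert table.values.loc["g1", "c1"] == 12.0

    def test_floor_at_or_above_ceiling_errors(self):
        frame = pd.DataFrame({"c1": [10.0]}, index=["g1"])
        with pytest.raises(ValueError, match="floor"):
            log10_heatmap(CountMatrix(frame, stage="averaged"), floor=10, ceiling=10)


class TestReportArithmetic:
    @pytest.mark.parametrize("num, den, expected", [
        (232, 1114, 20.8),
        (50, 1114, 4.5),
        (10233, 14757, 69.3),
        (0, 7, 0.0),
    ])
    def test_proportion_percent(self, num, den, expected):
        assert proportion_percent(num, den) == expected

    def test_proportion_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            proportion_percent(1, 0)

    def test_category_sums(self):
        assert category_sum([24, 16, 3, 2, 1, 8, 1, 1, 2, 13, 31, 2]) == 104
        assert category_sum([28, 4, 14, 10]) == 56
        assert category_sum([]) == 0

    def test_category_sum_rejects_negative(self):
        with pytest.raises(ValueError):
            category_sum([3, -1])
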