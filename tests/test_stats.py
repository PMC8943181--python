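import numpy as np
import pytest
import statsmodels.stats.power as smp

from conftest import make_summary, uniform_argmax_summaries
from orsmoke.errors import DecompositionError, GroupingError, ParameterError
from orsmoke.stats import (
    compare_groups,
    effect_decomposition,
    max_time_distribution,
    sample_size_two_group,
)


def summaries_with_response(values_by_group, factor="ses"):
    """One summary per value; factor level alternated by group."""
    levels = {"ses": ("with_ses", "without_ses"),
              "approach": ("open", "minimally_invasive"),
              "location": ("surgeon_level", "room_air")}[factor]
    out = []
    for level, values in zip(levels, values_by_group):
        for i, v in enumerate(values):
            out.append(
                make_summary(
                    f"{level}-{i}", **{factor: level},
                    harmful_total_mean_ppb=float(v),
                )
            )
    return out


class TestCompareGroups:
    def test_identical_groups_no_difference(self):
        summaries = summaries_with_response([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        result = compare_groups(summaries, "ses", "harmful_total_mean_ppb")
        assert result.mean_difference == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_label_swap_negates_difference(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(10, 2, 8), rng.normal(12, 3, 9)
        r1 = compare_groups(summaries_with_response([a, b]), "ses", "harmful_total_mean_ppb")
        r2 = compare_groups(summaries_with_response([b, a]), "ses", "harmful_total_mean_ppb")
        assert r1.mean_difference == pytest.approx(-r2.mean_difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_missing_level_is_grouping_error(self):
        summaries = summaries_with_response([[1.0, 2.0], []])
        with pytest.raises(GroupingError):
            compare_groups(summaries, "ses", "harmful_total_mean_ppb")

    def test_reports_group_means_and_sds(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0]
        result = compare_groups(summaries_with_response([a, b]), "ses", "harmful_total_mean_ppb")
        assert result.mean == (pytest.approx(2.0), pytest.approx(5.0))
        assert result.sd == (pytest.approx(1.0), pytest.approx(np.sqrt(2.0)))
        assert result.n == (3, 2)


class TestEffectDecomposition:
    def test_noise_free_linear_model_recovered_exactly(self):
        # response generated exactly from the indicator model
        beta = {"ses": -100.0, "approach": 40.0, "location": 25.0}
        intercept = 300.0
        rng = np.random.default_rng(0)
        summaries = []
        for i in range(40):
            ses = "with_ses" if rng.random() < 0.5 else "without_ses"
            approach = "open" if rng.random() < 0.5 else "minimally_invasive"
            location = "surgeon_level" if rng.random() < 0.5 else "room_air"
            y = (intercept + beta["ses"] * (ses == "with_ses")
                 + beta["approach"] * (approach == "open")
                 + beta["location"] * (location == "surgeon_level"))
            summaries.append(
                make_summary(f"op{i}", ses=ses, approach=approach, location=location,
                             harmful_total_mean_ppb=y)
            )
        result = effect_decomposition(summaries, "harmful_total_mean_ppb")
        for factor, value in beta.items():
            assert result.coefficients[factor] == pytest.approx(value, abs=1e-9)
        assert result.intercept == pytest.approx(intercept, abs=1e-9)
        assert result.multiple_r == pytest.approx(1.0, abs=1e-6)

    def test_single_factor_coefficient_is_group_mean_difference(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(10, 2, 12), rng.normal(14, 2, 10)
        summaries = summaries_with_response([a, b])
        result = effect_decomposition(summaries, "harmful_total_mean_ppb", factors=("ses",))
        assert result.coefficients["ses"] == pytest.approx(a.mean() - b.mean())
        assert result.intercept == pytest.approx(b.mean())

    def test_null_response_r_near_zero(self):
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(40):
            summaries = []
            for i in range(100):
                summaries.append(
                    make_summary(
                        f"op{i}",
                        ses="with_ses" if rng.random() < 0.5 else "without_ses",
                        approach="open" if rng.random() < 0.5 else "minimally_invasive",
                        location="surgeon_level" if rng.random() < 0.5 else "room_air",
                        harmful_total_mean_ppb=float(rng.normal()),
                    )
                )
            if effect_decomposition(summaries, "harmful_total_mean_ppb").multiple_r < 0.3:
                hits += 1
        assert hits >= 38  # R -> 0 for factor-independent responses

    def test_constant_factor_is_a_decomposition_error(self):
        summaries = summaries_with_response([[1.0, 2.0], [3.0, 4.0]])  # ses varies only
        with pytest.raises(DecompositionError, match="approach"):
            effect_decomposition(summaries, "harmful_total_mean_ppb",
                                 factors=("ses", "approach"))


class TestMaxTimeDistribution:
    def test_early_clustering_strongly_rejected(self):
        rng = np.random.default_rng(5)
        summaries = []
        for i in range(30):
            stats = {f"c{j}": (0.0, float(rng.uniform(1, 100)), float(rng.uniform(0, 0.1)))
                     for j in range(100)}
            summaries.append(make_summary(f"op{i}", channel_stats=stats))
        result = max_time_distribution(summaries, k=100)
        assert result.p_value < 1e-6
        assert result.n == 3000

    def test_k_caps_at_channel_count(self):
        summaries = [make_summary("op0", channel_stats={
            "a": (0.0, 1.0, 0.2), "b": (0.0, 2.0, 0.4), "c": (0.0, 3.0, 0.6)})]
        result = max_time_distribution(summaries, k=100)
        assert result.n == 3

    def test_selects_highest_concentration_channels(self):
        # channels beyond rank k have zero maxima and must not enter the pool
        stats = {"big1": (0.0, 10.0, 0.25), "big2": (0.0, 9.0, 0.75),
                 "zero1": (0.0, 0.0, 0.01), "zero2": (0.0, 0.0, 0.99)}
        result = max_time_distribution([make_summary("op0", channel_stats=stats)], k=2)
        assert sorted(result.fractions) == [0.25, 0.75]

    def test_invariant_to_channel_relabelling(self):
        rng = np.random.default_rng(8)
        stats = {f"c{j}": (0.0, float(rng.uniform(1, 10)), float(rng.uniform()))
                 for j in range(20)}
        renamed = {f"x{j}": v for j, v in enumerate(stats.values())}
        r1 = max_time_distribution([make_summary("op0", channel_stats=stats)], k=10)
        r2 = max_time_distribution([make_summary("op0", channel_stats=renamed)], k=10)
        assert r1.ks_statistic == pytest.approx(r2.ks_statistic)

    def test_uniform_null_calibration_small(self):
        rng = np.random.default_rng(12)
        rejections = sum(
            max_time_distribution(uniform_argmax_summaries(rng, n_ops=10, n_channels=5),
                                  k=100).p_value < 0.05
            for _ in range(100)
        )
        assert 1 <= rejections <= 12  # ~5 expected at the 0.05 level


class TestSampleSize:
    def test_design_effect_maps_to_fifteen_per_group(self):
        assert sample_size_two_group(1.22, 1.0, alpha=0.05, power=0.90) == 15

    def test_exact_method_agrees_with_statsmodels(self):
        for d in (0.5, 0.8, 1.22, 2.0):
            exact = sample_size_two_group(d, 1.0, method="exact")
            reference = int(np.ceil(smp.TTestIndPower().solve_power(
                effect_size=d, alpha=0.05, power=0.90)))
            assert exact == reference

    def test_brute_force_power_curve_brackets_the_answer(self):
        # Monte-Carlo power at the returned n is within sampling error of the
        # 90 % target, and clearly below target two sizes down
        from scipy import stats as sps

        d, n_reps = 1.22, 4000
        n = sample_size_two_group(d, 1.0)
        rng = np.random.default_rng(99)

        def mc_power(m):
            a = rng.normal(0.0, 1.0, size=(n_reps, m))
            b = rng.normal(d, 1.0, size=(n_reps, m))
            p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
            return float(np.mean(p < 0.05))

        assert abs(mc_power(n) - 0.90) < 0.03
        assert mc_power(n - 2) < 0.88

    def test_floor_of_two(self):
        assert sample_size_two_group(100.0, 1.0) == 2

    def test_halving_effect_roughly_quadruples_n(self):
        n1 = sample_size_two_group(1.0, 1.0)
        n2 = sample_size_two_group(0.5, 1.0)
        assert 3.5 <= n2 / n1 <= 4.5
        assert sample_size_two_group(0.25, 1.0) > n2

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            sample_size_two_group(0.0, 1.0)
        with pytest.raises(ParameterError):
            sample_size_two_group(1.0, -1.0)
        with pytest.raises(ParameterError):
            sample_size_two_group(1.0, 1.0, alpha=1.5)
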