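"""Z-scoring, smoothing, population profiles, and rank tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gestwear.config import AlignmentScheme
from gestwear.profiles import (
    age_threshold_comparison,
    annotate_p,
    baseline_stats,
    mann_whitney_u,
    pairwise_trimester_tests,
    population_profile,
    rolling_mean,
    trimester_means,
    zscore,
    zscore_series,
)


def _aligned(pregnancy_values: dict[str, dict[int, float]], series="temp_peak"):
    rows = [
        {"pregnancy_id": pid, "series": series, "day": day, "value": v}
        for pid, days in pregnancy_values.items()
        for day, v in days.items()
    ]
    return pd.DataFrame(rows)


class TestBaselineStats:
    def test_hand_computed_mean_and_sd(self):
        aligned = _aligned({"G1": {-50: 36.0, -45: 36.2, -40: 36.4, -38: 36.0, -35: 36.4}})
        out = baseline_stats(aligned)
        row = out.iloc[0]
        assert row["mu"] == pytest.approx(np.mean([36.0, 36.2, 36.4, 36.0, 36.4]))
        assert row["sigma"] == pytest.approx(np.std([36.0, 36.2, 36.4, 36.0, 36.4], ddof=1))
        assert row["usable"]

    def test_three_value_example(self):
        aligned = _aligned({"G1": {-50: 36.0, -45: 36.2, -40: 36.4, -38: 36.2, -35: 36.2}})
        row = baseline_stats(aligned).iloc[0]
        assert row["mu"] == pytest.approx(36.2)

    def test_constant_baseline_is_unusable(self):
        aligned = _aligned({"G1": {d: 36.2 for d in range(-55, -45)}})
        assert not baseline_stats(aligned)["usable"].iloc[0]

    def test_fewer_than_five_days_is_unusable(self):
        aligned = _aligned({"G1": {-50: 36.0, -45: 36.2, -40: 36.4, -35: 36.1}})
        assert not baseline_stats(aligned)["usable"].iloc[0]

    def test_days_outside_window_do_not_count(self):
        aligned = _aligned({"G1": {**{d: 36.0 + 0.01 * d for d in (-59, -50, -45, -40, -31)},
                                   -30: 99.0, -61: 99.0}})
        row = baseline_stats(aligned).iloc[0]
        assert row["n_days"] == 5
        assert row["mu"] < 40


class TestZScore:
    def test_value_at_mean_maps_to_zero_and_hand_example(self):
        s = pd.Series([36.2, 36.4], index=[0, 1])
        z = zscore_series(s, mu=36.2, sigma=0.2)
        assert z.loc[0] == pytest.approx(0.0)
        assert z.loc[1] == pytest.approx(1.0)

    def test_baseline_window_normalises_to_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        days = {d: 36.3 + rng.normal(0, 0.1) for d in range(-60, -30)}
        aligned = _aligned({"G1": days})
        stats_df = baseline_stats(aligned)
        z = zscore(aligned, stats_df)
        base = z[(z["day"] >= -60) & (z["day"] < -30)]["value"]
        assert abs(base.mean()) < 1e-9
        assert base.std(ddof=1) == pytest.approx(1.0)

    def test_double_normalisation_is_identity(self):
        rng = np.random.default_rng(1)
        aligned = _aligned({"G1": {d: rng.normal() for d in range(-60, 0)}})
        z1 = zscore(aligned, baseline_stats(aligned))
        z2 = zscore(z1, baseline_stats(z1))
        merged = z1.merge(z2, on=["pregnancy_id", "series", "day"], suffixes=("_1", "_2"))
        assert np.allclose(merged["value_1"], merged["value_2"], atol=1e-9)

    def test_unusable_baseline_rows_dropped(self):
        aligned = _aligned({"G1": {d: 36.2 for d in range(-60, 0)}})  # sigma 0
        z = zscore(aligned, baseline_stats(aligned))
        assert z.empty

    def test_zero_sigma_raises_for_single_series(self):
        with pytest.raises(ValueError, match="positive"):
            zscore_series(pd.Series([1.0]), mu=0.0, sigma=0.0)


class TestRollingMean:
    def test_window_one_is_identity(self):
        s = pd.Series([1.0, 5.0, 2.0], index=[3, 4, 9])
        pd.testing.assert_series_equal(rolling_mean(s, 1), s)

    def test_three_day_trailing_mean(self):
        s = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        out = rolling_mean(s, 3)
        assert out.loc[3] == pytest.approx(2.0)
        assert out.loc[1] == pytest.approx(1.0)  # min 1 observation

    def test_window_spans_calendar_days_across_gaps(self):
        s = pd.Series([10.0, 2.0], index=[1, 8])
        out = rolling_mean(s, 7)
        # day 8's trailing 7-day window covers days 2..8: only day 8 present
        assert out.loc[8] == pytest.approx(2.0)
        assert list(out.index) == [1, 8]


class TestPopulationProfile:
    def test_three_constant_series_give_interpolated_quantiles(self):
        aligned = _aligned({"G1": {0: 1.0}, "G2": {0: 2.0}, "G3": {0: 3.0}})
        prof = population_profile(aligned, seed=0)
        row = prof.iloc[0]
        assert row["median"] == 2.0
        assert row["q_lo"] == pytest.approx(1.2)
        assert row["q_hi"] == pytest.approx(2.8)
        assert row["ci_lo"] <= row["median"] <= row["ci_hi"]

    def test_single_series_profile_equals_series_with_degenerate_ci(self):
        aligned = _aligned({"G1": {0: 1.5, 1: 2.5}})
        prof = population_profile(aligned, seed=0).set_index("day")
        assert prof.loc[0, "median"] == 1.5 and prof.loc[1, "median"] == 2.5
        assert prof.loc[0, "ci_lo"] == prof.loc[0, "ci_hi"] == 1.5

    def test_bootstrap_ci_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        aligned = _aligned({f"G{i}": {0: rng.normal()} for i in range(10)})
        a = population_profile(aligned, seed=5)
        b = population_profile(aligned, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_median_matches_per_day_sort_oracle(self):
        rng = np.random.default_rng(3)
        aligned = _aligned(
            {f"G{i}": {d: rng.normal() for d in range(5)} for i in range(9)}
        )
        prof = population_profile(aligned, seed=0).set_index("day")
        for d in range(5):
            v = sorted(aligned.loc[aligned["day"] == d, "value"])
            assert prof.loc[d, "median"] == pytest.approx(v[len(v) // 2])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            population_profile(_aligned({}))


class TestTrimesterMeans:
    def test_filled_first_trimester_mean(self):
        aligned = _aligned({"G1": {d: float(i + 1) for i, d in enumerate(range(-28, 63))}})
        tm = trimester_means(aligned)
        t1 = tm[tm["trimester"] == 1]
        assert t1["value"].iloc[0] == pytest.approx(46.0)

    def test_constant_second_trimester(self):
        aligned = _aligned({"G1": {d: 36.3 for d in range(63, 154)}})
        tm = trimester_means(aligned)
        assert tm[tm["trimester"] == 2]["value"].iloc[0] == pytest.approx(36.3)
        assert 1 not in set(tm["trimester"])  # empty trimesters omitted


def enumeration_mwu_p(x, y):
    """Oracle: exact two-sided p by enumerating all rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_stat(sel):
        xs = pooled[list(sel)]
        ys = np.delete(pooled, list(sel))
        u = sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)
        return min(u, len(xs) * len(ys) - u)

    observed = u_stat(range(nx))
    total = count = 0
    for sel in combinations(range(len(pooled)), nx):
        total += 1
        if u_stat(sel) <= observed + 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_samples_enumeration_p_is_one(self):
        assert enumeration_mwu_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        r = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value > 0.9

    @pytest.mark.parametrize("nx,ny", [(3, 3), (3, 4), (4, 4), (3, 5), (4, 5), (5, 5)])
    def test_exact_path_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, nx + ny + 1)).astype(float)
            x, y = pooled[:nx], pooled[nx:]
            r = mann_whitney_u(x, y)
            assert r.p_value == pytest.approx(enumeration_mwu_p(x, y), abs=1e-9)

    def test_large_sample_path_close_to_exact(self):
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(10):
            x, y = rng.normal(size=8), rng.normal(size=8)
            from scipy import stats

            pe = stats.mannwhitneyu(x, y, method="exact").pvalue
            pa = mann_whitney_u(x, y).p_value  # n1*n2 = 64 falls on the exact path
            pa2 = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
            diffs.append(abs(pe - pa2))
            assert pe == pytest.approx(pa, abs=1e-12)
        assert np.mean(diffs) < 0.01
        assert max(diffs) < 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAnnotations:
    def test_bonferroni_boundary_for_four_comparisons(self):
        assert annotate_p(0.0125) == "*"
        assert annotate_p(0.01251) == "ns"
        assert 0.05 / 4 == 0.0125

    @pytest.mark.parametrize(
        "p,stars",
        [(0.5, "ns"), (0.01, "*"), (2.5e-3, "**"), (2.0e-4, "***"), (1e-6, "****")],
    )
    def test_star_ladder(self, p, stars):
        assert annotate_p(p) == stars


class TestTrimesterTests:
    def test_four_adjacent_comparisons_emitted(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in range(10):
            for t in (-1, 1, 2, 3, 4):
                rows.append({"pregnancy_id": f"G{pid}", "series": "temp_peak",
                             "value": rng.normal(), "trimester": t})
        out = pairwise_trimester_tests(pd.DataFrame(rows), "temp_peak")
        assert list(out["comparison"]) == ["-1 vs 1", "1 vs 2", "2 vs 3", "3 vs 4"]

    def test_sparse_trimester_comparison_omitted(self):
        rows = [{"pregnancy_id": "G0", "series": "temp_peak", "value": 1.0, "trimester": -1}]
        rows += [{"pregnancy_id": f"G{i}", "series": "temp_peak", "value": float(i),
                  "trimester": t} for i in range(4) for t in (1, 2)]
        out = pairwise_trimester_tests(pd.DataFrame(rows), "temp_peak")
        assert "-1 vs 1" not in set(out["comparison"])
        assert "1 vs 2" in set(out["comparison"])


class TestAgeComparison:
    @staticmethod
    def _survey(n, rng):
        bins = rng.choice(["30-34", "35-39"], size=n)
        return pd.DataFrame({"pregnancy_id": [f"G{i}" for i in range(n)], "age_bin": bins})

    def test_injected_offset_makes_most_bins_significant(self):
        rng = np.random.default_rng(0)
        survey = self._survey(24, rng)
        groups = survey.set_index("pregnancy_id")["age_bin"]
        rows = []
        for pid, age in groups.items():
            shift = 1.0 if age == "35-39" else 0.0
            for d in range(-28, 100):
                rows.append({"pregnancy_id": pid, "series": "temp_peak", "day": d,
                             "value": rng.normal(shift, 0.3)})
        out = age_threshold_comparison(pd.DataFrame(rows), survey, "temp_peak", bin_weeks=1,
                                       day_range=(-28, 100))
        assert out["significant"].mean() > 0.5

    def test_single_group_yields_no_bins(self):
        survey = pd.DataFrame({"pregnancy_id": ["G0"], "age_bin": ["30-34"]})
        rows = [{"pregnancy_id": "G0", "series": "temp_peak", "day": d, "value": 0.0}
                for d in range(10)]
        out = age_threshold_comparison(pd.DataFrame(rows), survey, "temp_peak")
        assert out.empty

    def test_four_week_bins_supported(self):
        rng = np.random.default_rng(1)
        survey = self._survey(16, rng)
        rows = [{"pregnancy_id": pid, "series": "temp_peak", "day": d,
                 "value": rng.normal()} for pid in survey["pregnancy_id"] for d in range(0, 56)]
        out = age_threshold_comparison(pd.DataFrame(rows), survey, "temp_peak", bin_weeks=4,
                                       day_range=(0, 56))
        assert len(out) == 2  # two 4-week bins
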