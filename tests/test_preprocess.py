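"""Raw-stream cleaning: dedup, filters, wear gating, daily aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gestwear.config import PreprocessConfig, SimulationConfig
from gestwear.preprocess import (
    _band_mean,
    annotate_sleep,
    daily_aggregate,
    load_and_normalize,
    met_gate_filter,
    preprocess_pipeline,
    quantile_filter,
    select_longest_sleep,
)
from gestwear.simulate import PregnancySpec, simulate_minute_stream, simulate_pregnancy_series


def _samples(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "timestamp_local", "modality", "value"])
    df["pregnancy_id"] = "G1"
    df["timestamp_local"] = pd.to_datetime(df["timestamp_local"])
    return df[["participant_id", "pregnancy_id", "timestamp_local", "modality", "value"]]


class TestLoadAndNormalize:
    def test_duplicates_collapse_and_rows_sort(self):
        rows = [
            ("P1", "2020-01-01 10:02", "temperature", 36.2),
            ("P1", "2020-01-01 10:00", "temperature", 36.1),
            ("P1", "2020-01-01 10:00", "temperature", 36.9),  # duplicate timestamp
            ("P1", "2020-01-01 10:01", "temperature", 36.15),
            ("P1", "2020-01-01 10:01", "temperature", 36.15),  # exact duplicate
        ]
        out = load_and_normalize(_samples(rows))
        assert len(out) == 3
        assert out["timestamp_local"].is_monotonic_increasing
        # first occurrence kept for the duplicated 10:00 stamp
        assert out.loc[out["timestamp_local"] == "2020-01-01 10:00", "value"].iloc[0] == 36.1

    def test_mostly_unparseable_input_raises(self):
        df = pd.DataFrame(
            {
                "participant_id": "P1",
                "pregnancy_id": "G1",
                "timestamp_local": ["not-a-time"] * 9 + ["2020-01-01 10:00"],
                "modality": "temperature",
                "value": 36.0,
            }
        )
        with pytest.raises(ValueError, match="rejected"):
            load_and_normalize(df)


class TestSelectLongestSleep:
    @staticmethod
    def _sleep(rows):
        return pd.DataFrame(
            rows, columns=["participant_id", "date", "sleep_start", "sleep_end", "duration_s"]
        )

    def test_longest_duration_kept(self):
        sleep = self._sleep(
            [
                ("P1", "2020-01-01", "2020-01-01 23:00", "2020-01-02 05:00", 21600),
                ("P1", "2020-01-01", "2020-01-01 22:00", "2020-01-02 06:00", 28800),
            ]
        )
        out = select_longest_sleep(sleep)
        assert len(out) == 1 and out["duration_s"].iloc[0] == 28800

    def test_single_row_is_identity(self):
        sleep = self._sleep([("P1", "2020-01-01", "2020-01-01 23:00", "2020-01-02 07:00", 28800)])
        out = select_longest_sleep(sleep)
        assert len(out) == 1 and out["duration_s"].iloc[0] == 28800

    def test_duration_tie_broken_by_earliest_start(self):
        sleep = self._sleep(
            [
                ("P1", "2020-01-01", "2020-01-01 23:00", "2020-01-02 07:00", 28800),
                ("P1", "2020-01-01", "2020-01-01 22:00", "2020-01-02 06:00", 28800),
            ]
        )
        out = select_longest_sleep(sleep)
        assert out["sleep_start"].iloc[0] == pd.Timestamp("2020-01-01 22:00")


class TestQuantileFilter:
    def test_five_ninetyfive_on_one_to_hundred_keeps_ninety(self):
        rows = [
            ("P1", f"2020-01-01 {h:02d}:{m:02d}", "temperature", float(v))
            for v, (h, m) in zip(range(1, 101), [(i // 60, i % 60) for i in range(100)])
        ]
        out = quantile_filter(_samples(rows), 0.05, 0.95)
        assert len(out) == 90
        assert out["value"].min() == 6 and out["value"].max() == 95

    def test_constant_series_unchanged(self):
        rows = [("P1", f"2020-01-01 00:{m:02d}", "temperature", 36.0) for m in range(20)]
        out = quantile_filter(_samples(rows), 0.05, 0.95)
        assert len(out) == 20

    def test_zero_one_is_identity(self):
        rows = [("P1", f"2020-01-01 00:{m:02d}", "temperature", float(m)) for m in range(20)]
        out = quantile_filter(_samples(rows), 0.0, 1.0)
        assert len(out) == 20

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=120),
        low=st.floats(0.0, 0.4),
        span=st.floats(0.2, 1.0),
    )
    def test_drop_count_bounded_by_band_mass(self, values, low, span):
        high = min(low + span, 1.0)
        if not low < high:
            return
        rows = [
            ("P1", pd.Timestamp("2020-01-01") + pd.Timedelta(minutes=i), "temperature", v)
            for i, v in enumerate(values)
        ]
        out = quantile_filter(_samples(rows), low, high)
        n = len(values)
        assert n - len(out) <= (low + (1 - high)) * n + 2


class TestMetGate:
    def test_sample_dropped_when_paired_met_below_gate(self):
        rows = [
            ("P1", "2020-01-01 02:00", "temperature", 36.2),
            ("P1", "2020-01-01 02:00", "met", 0.4),
        ]
        out = met_gate_filter(_samples(rows))
        assert (out["modality"] == "temperature").sum() == 0
        assert (out["modality"] == "met").sum() == 1  # MET itself never gated

    def test_met_exactly_at_gate_retains_sample(self):
        rows = [
            ("P1", "2020-01-01 02:00", "temperature", 36.2),
            ("P1", "2020-01-01 02:00", "met", 0.5),
        ]
        out = met_gate_filter(_samples(rows))
        assert (out["modality"] == "temperature").sum() == 1

    def test_no_met_stream_retains_everything(self):
        rows = [("P1", "2020-01-01 02:00", "temperature", 36.2)]
        out = met_gate_filter(_samples(rows))
        assert len(out) == 1

    def test_met_outside_tolerance_does_not_gate(self):
        rows = [
            ("P1", "2020-01-01 02:00:00", "temperature", 36.2),
            ("P1", "2020-01-01 02:05:00", "met", 0.1),  # 300 s away
        ]
        out = met_gate_filter(_samples(rows))
        assert (out["modality"] == "temperature").sum() == 1


class TestAnnotateSleep:
    sleep = pd.DataFrame(
        {
            "participant_id": ["P1"],
            "date": ["2020-01-01"],
            "sleep_start": [pd.Timestamp("2020-01-01 23:00")],
            "sleep_end": [pd.Timestamp("2020-01-02 07:00")],
            "duration_s": [28800],
        }
    )

    @pytest.mark.parametrize(
        "stamp,expected",
        [
            ("2020-01-02 01:00", True),
            ("2020-01-02 07:00", False),  # half-open at sleep_end
            ("2020-01-01 12:00", False),
        ],
    )
    def test_flag_follows_half_open_interval(self, stamp, expected):
        rows = [("P1", stamp, "temperature", 36.0)]
        out = annotate_sleep(_samples(rows), self.sleep)
        assert bool(out["asleep"].iloc[0]) is expected

    def test_night_without_summary_is_awake(self):
        rows = [("P2", "2020-01-02 01:00", "temperature", 36.0)]
        out = annotate_sleep(_samples(rows), self.sleep)
        assert not out["asleep"].iloc[0]


def brute_force_band_mean(values, lo, hi):
    """Oracle: sort, select midpoint-rank band, average (fallback quantile)."""
    v = sorted(values)
    n = len(v)
    band = [x for i, x in enumerate(v, start=1) if lo <= (i - 0.5) / n <= hi]
    if band:
        return float(np.mean(band))
    return float(np.quantile(v, (lo + hi) / 2))


class TestDailyAggregate:
    def test_peak_and_trough_rank_bands_on_1_to_200(self):
        assert _band_mean(np.arange(1, 201), 0.90, 0.95) == pytest.approx(185.5)
        assert _band_mean(np.arange(1, 201), 0.05, 0.10) == pytest.approx(15.5)

    def test_constant_series_collapses_all_statistics(self):
        rows = [("P1", f"2020-01-01 10:{m:02d}", "temperature", 36.0) for m in range(30)]
        out = daily_aggregate(_samples(rows), "h24")
        r = out.iloc[0]
        assert r["mean"] == r["median"] == r["peak"] == r["trough"] == 36.0

    def test_nightly_window_membership_is_half_open(self):
        rows = [
            ("P1", "2020-01-01 20:00", "temperature", 36.0),  # belongs to Jan 1 night
            ("P1", "2020-01-02 07:59", "temperature", 36.0),  # still Jan 1 night
            ("P1", "2020-01-02 08:00", "temperature", 36.0),  # outside any night of Jan 1
        ]
        out = daily_aggregate(_samples(rows), "nightly")
        jan1 = out[out["date"] == pd.Timestamp("2020-01-01")]
        assert jan1["n_samples"].iloc[0] == 2

    def test_ordering_invariant_trough_median_peak(self):
        rng = np.random.default_rng(4)
        rows = [
            ("P1", pd.Timestamp("2020-01-01") + pd.Timedelta(minutes=i), "temperature", v)
            for i, v in enumerate(rng.normal(36, 0.5, 500))
        ]
        out = daily_aggregate(_samples(rows), "h24")
        assert (out["trough"] <= out["median"] + 1e-12).all()
        assert (out["median"] <= out["peak"] + 1e-12).all()

    @pytest.mark.parametrize("n", [1, 2, 5, 17, 100, 500])
    def test_band_mean_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        v = rng.normal(size=n)
        for lo, hi in ((0.90, 0.95), (0.05, 0.10)):
            assert _band_mean(v, lo, hi) == pytest.approx(brute_force_band_mean(v, lo, hi))

    def test_endpoint_mean_definition_available(self):
        cfg = PreprocessConfig(peak_definition="endpoint_mean")
        v = np.arange(1, 101)
        expected = (np.quantile(v, 0.90) + np.quantile(v, 0.95)) / 2
        assert _band_mean(v, 0.90, 0.95, "endpoint_mean") == pytest.approx(expected)


@pytest.fixture(scope="module")
def raw():
    cfg = SimulationConfig(nonwear_rate=0.08, missing_day_rate=0.0)
    spec = PregnancySpec("P1", "G1", "30-34", "2020-06-01", "2021-02-15", "full_term")
    daily = simulate_pregnancy_series(spec, cfg, seed=13).loc[0:3]
    return simulate_minute_stream(daily, spec, cfg, seed=13)


class TestPipeline:
    def test_met_gate_removes_nonwear_blocks(self, raw):
        samples, _ = raw
        clean = load_and_normalize(samples)
        met = clean[clean["modality"] == "met"]
        nonwear_stamps = set(met.loc[met["value"] < 0.5, "timestamp_local"])
        temp = clean[clean["modality"] == "temperature"]
        inside_before = temp["timestamp_local"].isin(nonwear_stamps).sum()
        gated = met_gate_filter(clean)
        temp_after = gated[gated["modality"] == "temperature"]
        inside_after = temp_after["timestamp_local"].isin(nonwear_stamps).sum()
        assert inside_before > 0
        assert inside_after <= 0.05 * inside_before

    def test_full_pipeline_emits_both_windows_and_valid_rows(self, raw):
        samples, sleep = raw
        out = preprocess_pipeline(samples, sleep)
        assert set(out["window"]) == {"h24", "nightly"}
        assert (out["trough"] <= out["median"] + 1e-9).all()
        assert (out["median"] <= out["peak"] + 1e-9).all()
        assert (out["n_samples"] >= 1).all()

    def test_nightly_temperature_peak_tracks_simulated_daily_value(self, raw):
        samples, sleep = raw
        out = preprocess_pipeline(samples, sleep)
        nightly_temp = out[
            (out["window"] == "nightly")
            & (out["modality"] == "temperature")
            & (out["n_samples"] >= 300)  # full nights only (last night is truncated)
        ]
        # simulated nightly peak sits near 36.3-37.1 degC; ambient non-wear
        # values (24-28 degC) must not survive into the aggregate
        assert len(nightly_temp) >= 3
        assert nightly_temp["peak"].between(35.0, 38.5).all()
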