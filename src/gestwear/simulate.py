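"""Synthetic wearable-pregnancy cohort generator.

Real ring-derived pregnancy data cannot be redistributed, so every
downstream analysis stage in this package is exercised against cohorts
drawn from this module.  The generator emits three layers:

* survey rows (one per pregnancy: anchor dates, age bin, outcome,
  high-risk flag),
* daily analysis series (the six nightly/24 h aggregates the analyses
  consume), and
* optional minute-level raw sample streams plus per-night sleep
  summaries, for exercising the raw preprocessing stage.

Trajectory shapes are piecewise linear with plateaus, anchored at
conception (modelled 28 days before the date the pregnancy became known,
DKP): a ~28-day cyclic nightly-peak temperature before conception, a
post-conception plateau above the cycle peak for roughly eight weeks
followed by a slow decline to below the pre-pregnancy mean at delivery,
an opposite-signed nightly-trough trend, a heart-rate local peak 14 days
after conception with a later pre-delivery rise, mirrored HRV, mild
respiratory-rate and activity declines, and postpartum recovery.  Early
fetal loss (EFL) replaces the trajectory from the loss day onward with a
linear nightly-peak temperature decline whose per-day magnitude shrinks
with the loss day.

A ``fixture`` cohort reproduces the study's subject bookkeeping exactly
(704 reported pregnancies; 224 delivered in-window of which 97 survive
eligibility filters; 34 reported EFLs of which 23 survive), including the
per-age-bin counts of the included pregnancies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import json
import numpy as np
import pandas as pd

from .config import (
    AGE_BINS,
    EFL_OUTCOMES,
    SERIES_KEYS,
    SimulationConfig,
)

# Wearable data-collection window of the study cohort.
DATA_WINDOW = (pd.Timestamp("2019-09-01"), pd.Timestamp("2022-02-28"))

# Conception is modelled this many days before DKP.
CONCEPTION_OFFSET = -28

# Included-pregnancy age-bin bookkeeping used by the fixture cohort:
# bin -> (full-term all, full-term high-risk, EFL all, EFL high-risk).
FIXTURE_AGE_TABLE: Mapping[str, tuple[int, int, int, int]] = {
    "25-29": (13, 2, 1, 0),
    "30-34": (36, 2, 5, 0),
    "35-39": (29, 4, 14, 5),
    "40-44": (17, 7, 3, 2),
    "45-49": (2, 2, 0, 0),
}

# Fixture exclusion counts: delivered arm and EFL arm.
FIXTURE_COUNTS = {
    "partner_report": 52,
    "out_of_window": 392,
    "delivered": 224,
    "delivered_sparse_trimester": 47,
    "delivered_sparse_other": 76,
    "delivered_preterm": 4,
    "efl_reported": 34,
    "efl_failure_to_implant": 4,
    "efl_low_first_trimester": 3,
    "efl_low_prior_completeness": 4,
}


@dataclass
class PregnancySpec:
    """One pregnancy's survey-level description."""

    participant_id: str
    pregnancy_id: str
    age_bin: str
    dkp: pd.Timestamp
    dps: pd.Timestamp
    outcome: str
    high_risk: bool = False
    exclude_hint: str = "none"  # none | sparse_other | low_prior_completeness

    def __post_init__(self) -> None:
        self.dkp = pd.Timestamp(self.dkp)
        self.dps = pd.Timestamp(self.dps)
        if self.age_bin not in AGE_BINS:
            raise ValueError(f"unknown age bin {self.age_bin!r}")
        if self.outcome in EFL_OUTCOMES:
            loss_day = (self.dps - self.dkp).days
            if not 0 < loss_day < 91:
                raise ValueError(
                    f"EFL pregnancy {self.pregnancy_id}: dps - dkp = {loss_day} days "
                    "must fall inside the first trimester"
                )
        elif self.outcome in ("full_term", "preterm") and self.dps <= self.dkp:
            raise ValueError(f"pregnancy {self.pregnancy_id}: dps must follow dkp")

    @property
    def loss_day(self) -> int:
        return (self.dps - self.dkp).days

    @property
    def is_efl(self) -> bool:
        return self.outcome in EFL_OUTCOMES


@dataclass
class SyntheticCohort:
    """Bundle of survey rows, daily series, optional raw streams, and truth."""

    survey: pd.DataFrame
    daily: pd.DataFrame
    truth: dict
    samples: pd.DataFrame | None = None
    sleep: pd.DataFrame | None = None

    def write(self, out_dir: str | Path, fmt: str = "csv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.survey.to_csv(out / "survey.csv", index=False)
        if fmt == "parquet":
            self.daily.to_parquet(out / "daily.parquet", index=False)
            if self.samples is not None:
                self.samples.to_parquet(out / "samples.parquet", index=False)
        else:
            self.daily.to_csv(out / "daily.csv", index=False)
            if self.samples is not None:
                self.samples.to_csv(out / "samples.csv", index=False)
        if self.sleep is not None:
            self.sleep.to_csv(out / "sleep.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Trajectory model


def _cycle_delta(days: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Pre-conception cyclic nightly-peak temperature offset (degC).

    Triangle wave with its minimum at each cycle start (menstruation) and
    apex late in the cycle (luteal plateau); conception coincides with a
    cycle start, so the last pre-conception trough sits 28 days before DKP.
    """
    length = cfg.cycle_length_days
    apex = round(0.571 * length)  # 16 for a 28-day cycle
    phase = np.mod(days - CONCEPTION_OFFSET, length)
    rising = phase <= apex
    tri = np.where(rising, phase / apex, (length - phase) / (length - apex))
    return cfg.luteal_amplitude * tri


def _interp_segments(days: np.ndarray, points: list[tuple[float, float]]) -> np.ndarray:
    xs, ys = zip(*points)
    return np.interp(days, xs, ys)


def _control_points(key: str, dps_day: int, cfg: SimulationConfig) -> list[tuple[float, float]]:
    """Piecewise-linear control points (day relative to DKP, delta) for the
    post-conception portion of each series' trajectory."""
    c = CONCEPTION_OFFSET
    amp, rise = cfg.luteal_amplitude, cfg.conception_rise
    plateau_end = min(56, dps_day - 1)  # ~8 weeks of plateau after DKP
    if key == "temp_peak":
        return [
            (c, 0.0),
            (c + 14, amp + rise),
            (plateau_end, amp + rise),
            (dps_day, -0.05),  # below the pre-pregnancy mean at delivery
            (dps_day + 42, amp / 2.0),
            (dps_day + 365, amp / 2.0),
        ]
    if key == "temp_trough":
        return [
            (c, 0.0),
            (c + 14, -0.5),
            (dps_day, 1.2),
            (dps_day + 42, 0.0),
            (dps_day + 365, 0.0),
        ]
    if key == "hr_peak":
        return [
            (c, 0.0),
            (c + 14, 3.0),  # local peak 14 days after conception
            (14, 1.0),
            (max(15, dps_day - 21), 8.0),
            (dps_day, 5.0),
            (dps_day + 14, 0.0),
            (dps_day + 365, 0.0),
        ]
    if key == "hrv_peak":
        return [
            (c, 0.0),
            (c + 14, -4.0),
            (14, -1.5),
            (max(15, dps_day - 21), -12.0),
            (dps_day, -8.0),
            (dps_day + 14, 2.0),
            (dps_day + 60, 0.0),
            (dps_day + 365, 0.0),
        ]
    if key == "rr_peak":
        return [(c, 0.0), (dps_day, -0.5), (dps_day + 42, 0.0), (dps_day + 365, 0.0)]
    if key == "met_peak":
        return [(c, 0.0), (dps_day, -0.25), (dps_day + 42, 0.0), (dps_day + 365, 0.0)]
    raise KeyError(key)


def _noiseless_deltas(days: np.ndarray, dps_day: int, cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Noise-free per-series trajectory offsets on an integer day grid."""
    out: dict[str, np.ndarray] = {}
    pre = days < CONCEPTION_OFFSET
    for key in SERIES_KEYS:
        delta = _interp_segments(days.astype(float), _control_points(key, dps_day, cfg))
        if key == "temp_peak":
            delta = np.where(pre, _cycle_delta(days, cfg), delta)
        else:
            delta = np.where(pre, 0.0, delta)
        out[key] = delta
    return out


def simulate_pregnancy_series(
    spec: PregnancySpec,
    cfg: SimulationConfig,
    seed: int,
    noiseless: bool = False,
    return_truth: bool = False,
):
    """Daily analysis series for one pregnancy, days -pre_days..dps+postpartum.

    Returns a DataFrame indexed by integer day relative to DKP with one
    column per series key.  EFL outcomes are simulated with a nominal
    full-term trajectory; callers inject the loss with :func:`inject_efl`
    (the cohort generator does this automatically).  Identical
    ``(spec, cfg, seed)`` yield identical output.
    """
    if spec.dps < spec.dkp and not spec.is_efl:
        raise ValueError(f"pregnancy {spec.pregnancy_id}: dps precedes dkp")
    dps_day = spec.loss_day if not spec.is_efl else CONCEPTION_OFFSET + 280
    end_day = (spec.loss_day if spec.is_efl else dps_day) + cfg.postpartum_days
    days = np.arange(-cfg.pre_days, end_day + 1)
    deltas = _noiseless_deltas(days, dps_day, cfg)

    rng = np.random.default_rng(seed)
    offsets = {
        key: (0.0 if noiseless else rng.normal(0.0, cfg.between_subject_sd[key]))
        for key in SERIES_KEYS
    }
    data = {}
    for key in SERIES_KEYS:
        base = cfg.baselines[key] + offsets[key]
        noise = 0.0 if noiseless else rng.normal(0.0, cfg.noise_sd[key], size=days.size)
        data[key] = base + deltas[key] + noise
    frame = pd.DataFrame(data, index=pd.Index(days, name="day"))
    if not return_truth:
        return frame
    truth = {
        "baselines": {k: cfg.baselines[k] + offsets[k] for k in SERIES_KEYS},
        "dps_day_nominal": int(dps_day),
        "conception_day": CONCEPTION_OFFSET,
    }
    return frame, truth


def inject_efl(
    series: pd.DataFrame,
    loss_day: int,
    cfg: SimulationConfig,
    baselines: Mapping[str, float] | None = None,
    relax_tau_days: float = 10.0,
    sigma: float | None = None,
) -> pd.DataFrame:
    """Overwrite a trajectory from ``loss_day`` onward with post-loss decline.

    The nightly peak temperature declines linearly toward the pre-pregnancy
    baseline with per-day magnitude ``efl_slope_intercept -
    efl_slope_per_day * loss_day`` (losses later in the first trimester
    decline more slowly), clipped at baseline; all other series relax
    exponentially to baseline with time constant ``relax_tau_days``.

    With ``cfg.efl_slope_units == "z"`` (default) the configured slope is
    in units of the pregnancy's own -60..-30 day baseline SD per day — the
    scale on which the downstream loss analysis operates — and is
    converted to degC/day using ``sigma`` when given, else the SD
    estimated from the series itself.
    """
    if not 0 < loss_day < 91:
        raise ValueError(f"loss_day must lie inside the first trimester, got {loss_day}")
    if baselines is None:
        baselines = cfg.baselines
    out = series.copy()
    days = out.index.to_numpy()
    post = days >= loss_day
    if not post.any():
        return out
    slope = efl_post_loss_slope(loss_day, cfg)
    if cfg.efl_slope_units == "z":
        slope *= sigma if sigma is not None else _baseline_sigma(out["temp_peak"], cfg)
    elapsed = (days[post] - loss_day).astype(float)
    for key in SERIES_KEYS:
        floor = baselines[key]
        v_loss = float(np.interp(loss_day, days, out[key].to_numpy()))
        if key == "temp_peak":
            vals = v_loss - slope * elapsed
            vals = np.maximum(vals, floor) if v_loss >= floor else np.full_like(vals, v_loss)
        else:
            vals = floor + (v_loss - floor) * np.exp(-elapsed / relax_tau_days)
        out.loc[post, key] = vals
    return out


def efl_post_loss_slope(loss_day: int, cfg: SimulationConfig) -> float:
    """Magnitude (in ``cfg.efl_slope_units`` per day) of the post-loss
    nightly-peak temperature decline."""
    return max(cfg.efl_slope_intercept - cfg.efl_slope_per_day * loss_day, 0.0)


def _baseline_sigma(temp_peak: pd.Series, cfg: SimulationConfig) -> float:
    """SD of nightly peak temperature over the -60..-30 day baseline window,
    falling back to the noise-free cycle model when the window is absent."""
    window = temp_peak[(temp_peak.index >= -60) & (temp_peak.index < -30)].dropna()
    if len(window) >= 2 and window.std(ddof=1) > 0:
        return float(window.std(ddof=1))
    model = _cycle_delta(np.arange(-60, -30), cfg)
    return float(max(np.std(model, ddof=1), 1e-6))


# ---------------------------------------------------------------------------
# Minute-level raw streams


def simulate_minute_stream(
    series: pd.DataFrame,
    spec: PregnancySpec,
    cfg: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw sample streams and sleep summaries consistent with a daily series.

    Temperature and MET are emitted at 1-minute cadence around the clock;
    HR and HRV at 5-minute and RR at 30-second cadence only inside the
    night's sleep interval.  Non-wear is injected as contiguous 30-240
    minute blocks with MET drawn in [0, 0.5) and ambient (physiologically
    implausible) temperature, at an expected minute fraction of
    ``cfg.nonwear_rate``.  Each night yields one sleep-summary row, plus an
    occasional shorter duplicate to exercise longest-sleep selection.
    """
    rng = np.random.default_rng(seed)
    sample_rows: list[pd.DataFrame] = []
    sleep_rows: list[dict] = []
    if series.empty:
        empty_samples = pd.DataFrame(
            columns=["participant_id", "pregnancy_id", "timestamp_local", "modality", "value"]
        )
        empty_sleep = pd.DataFrame(
            columns=["participant_id", "date", "sleep_start", "sleep_end", "duration_s"]
        )
        return empty_samples, empty_sleep

    minutes = np.arange(1440)
    hours = minutes / 60.0
    # Circadian shapes: temperature peaks at night (~03:00), activity by day
    # (~15:00); chosen so the nightly and 24 h windows differ measurably.
    temp_shape = np.cos(2 * np.pi * (hours - 3.0) / 24.0)
    act_shape = np.clip(np.cos(2 * np.pi * (hours - 15.0) / 24.0), 0.0, None)

    for day, row in series.iterrows():
        day_date = spec.dkp + pd.Timedelta(days=int(day))
        t0 = pd.Timestamp(day_date)
        stamps = t0 + pd.to_timedelta(minutes, unit="m")

        peak, trough = row["temp_peak"], row["temp_trough"]
        mid, amp = (peak + trough) / 2.0, (peak - trough) / 2.0
        temp = mid + amp * temp_shape + rng.normal(0.0, 0.05, 1440)
        met = 0.9 + 0.1 * row["met_peak"] + (row["met_peak"] - 1.0) * act_shape
        met = np.maximum(met + rng.normal(0.0, 0.1, 1440), 0.7)

        # Non-wear blocks: contiguous, MET < 0.5, ambient temperature.
        target = cfg.nonwear_rate * 1440
        covered = 0
        nonwear = np.zeros(1440, dtype=bool)
        while covered < target:
            length = int(rng.integers(30, 241))
            start = int(rng.integers(0, 1440))
            stop = min(start + length, 1440)
            nonwear[start:stop] = True
            covered = int(nonwear.sum())
            if covered >= 1440:
                break
        if nonwear.any():
            met[nonwear] = rng.uniform(0.0, 0.5, nonwear.sum())
            temp[nonwear] = rng.uniform(24.0, 28.0, nonwear.sum())

        sample_rows.append(_stack(spec, stamps, "temperature", temp))
        sample_rows.append(_stack(spec, stamps, "met", met))

        # Sleep interval: ~23:00 to ~07:00 next day, jittered.
        start = t0 + pd.Timedelta(hours=23) + pd.Timedelta(minutes=int(rng.integers(-30, 31)))
        end = t0 + pd.Timedelta(hours=31) + pd.Timedelta(minutes=int(rng.integers(-30, 31)))
        sleep_rows.append(
            {
                "participant_id": spec.participant_id,
                "date": day_date.date(),
                "sleep_start": start,
                "sleep_end": end,
                "duration_s": int((end - start).total_seconds()),
            }
        )
        if rng.random() < 0.15:  # shorter duplicate row for the same night
            dup_start = start + pd.Timedelta(hours=2)
            dup_end = end - pd.Timedelta(hours=3)
            sleep_rows.append(
                {
                    "participant_id": spec.participant_id,
                    "date": day_date.date(),
                    "sleep_start": dup_start,
                    "sleep_end": dup_end,
                    "duration_s": int((dup_end - dup_start).total_seconds()),
                }
            )

        hr5 = pd.date_range(start.ceil("5min"), end, freq="5min", inclusive="left")
        rr30 = pd.date_range(start.ceil("30s"), end, freq="30s", inclusive="left")
        night_frac = np.linspace(0.0, 1.0, hr5.size) if hr5.size else np.array([])
        hr_vals = row["hr_peak"] - 4.0 + 4.0 * np.cos(np.pi * night_frac) ** 2
        sample_rows.append(_stack(spec, hr5, "hr", hr_vals + rng.normal(0.0, 1.0, hr5.size)))
        hrv_vals = row["hrv_peak"] - 8.0 + 8.0 * np.sin(np.pi * night_frac) ** 2
        sample_rows.append(_stack(spec, hr5, "hrv", hrv_vals + rng.normal(0.0, 3.0, hr5.size)))
        rr_vals = row["rr_peak"] - 0.5 + rng.normal(0.0, 0.3, rr30.size)
        sample_rows.append(_stack(spec, rr30, "rr", rr_vals))

    samples = pd.concat(sample_rows, ignore_index=True)
    sleep = pd.DataFrame(sleep_rows)
    return samples, sleep


def _stack(spec: PregnancySpec, stamps, modality: str, values) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": spec.participant_id,
            "pregnancy_id": spec.pregnancy_id,
            "timestamp_local": stamps,
            "modality": modality,
            "value": np.asarray(values, dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Cohort assembly


def _daily_long(spec: PregnancySpec, series: pd.DataFrame) -> pd.DataFrame:
    frame = series.reset_index().melt(id_vars="day", var_name="series", value_name="value")
    frame["date"] = spec.dkp + pd.to_timedelta(frame["day"], unit="D")
    frame["participant_id"] = spec.participant_id
    frame["pregnancy_id"] = spec.pregnancy_id
    return frame[["participant_id", "pregnancy_id", "date", "series", "value"]]


def _drop_days(series: pd.DataFrame, rng: np.random.Generator, rate: float) -> pd.DataFrame:
    if rate <= 0:
        return series
    keep = rng.random(len(series)) >= rate
    return series.loc[keep]


def _simulate_one(
    spec: PregnancySpec,
    cfg: SimulationConfig,
    seed: int,
    drop_window: tuple[int, int] | None = None,
    drop_keep_frac: float = 0.15,
    no_preonset: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Noiseless trajectory + EFL injection + noise + missingness for one spec."""
    noiseless = simulate_pregnancy_series(spec, cfg, seed, noiseless=True)
    truth: dict = {"conception_day": CONCEPTION_OFFSET, "outcome": spec.outcome}
    if spec.is_efl:
        loss = spec.loss_day
        slope = efl_post_loss_slope(loss, cfg)
        sigma = None
        if cfg.efl_slope_units == "z":
            # SD of the baseline window as the analysis will observe it:
            # cycle variability plus day-level measurement noise.
            sigma = math.hypot(
                _baseline_sigma(noiseless["temp_peak"], cfg), cfg.noise_sd["temp_peak"]
            )
            slope *= sigma
        noiseless = inject_efl(noiseless, loss, cfg, sigma=sigma)
        v_loss = float(noiseless.loc[noiseless.index >= loss, "temp_peak"].iloc[0])
        floor = cfg.baselines["temp_peak"]
        n_decline = int(math.floor((v_loss - floor) / slope)) if slope > 0 else 0
        truth.update(
            {"loss_day": loss, "efl_slope_degc": -slope, "n_decline_days": n_decline}
        )
    rng = np.random.default_rng(seed)
    offsets = {k: rng.normal(0.0, cfg.between_subject_sd[k]) for k in SERIES_KEYS}
    noisy = noiseless.copy()
    for key in SERIES_KEYS:
        noisy[key] = noisy[key] + offsets[key] + rng.normal(0.0, cfg.noise_sd[key], len(noisy))
    truth["baseline_offsets"] = offsets

    frame = noisy
    if no_preonset:
        frame = frame.loc[frame.index >= CONCEPTION_OFFSET]
    frame = _drop_days(frame, rng, cfg.missing_day_rate)
    if drop_window is not None:
        lo, hi = drop_window
        in_win = (frame.index >= lo) & (frame.index < hi)
        keep = ~in_win | (rng.random(len(frame)) < drop_keep_frac)
        frame = frame.loc[keep]
    return frame, truth


def _survey_frame(specs: Iterable[PregnancySpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "pregnancy_id": s.pregnancy_id,
                "age_bin": s.age_bin,
                "dkp": s.dkp,
                "dps": s.dps,
                "outcome": s.outcome,
                "high_risk": s.high_risk,
                "exclude_hint": s.exclude_hint,
            }
            for s in specs
        ]
    )


def _sample_age_bin(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    labels = [b for b, _ in cfg.age_bins]
    probs = np.array([p for _, p in cfg.age_bins])
    return str(rng.choice(labels, p=probs / probs.sum()))


def simulate_cohort(
    cfg: SimulationConfig,
    seed: int,
    fixture: bool = False,
    minute_pregnancies: int = 0,
) -> SyntheticCohort:
    """Draw a full synthetic cohort (survey + daily series + truth).

    With ``fixture=True`` the survey bookkeeping reproduces the study's
    subject accounting exactly (including which pregnancies the eligibility
    filters must remove); otherwise ``cfg.n_full_term`` clean full-term and
    ``cfg.n_efl`` clean EFL pregnancies are drawn.
    """
    if fixture:
        specs, gen_flags = _fixture_specs(seed)
    else:
        specs, gen_flags = _random_specs(cfg, seed)

    ss = np.random.SeedSequence([seed, 0xC0F0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(specs))]

    daily_frames: list[pd.DataFrame] = []
    truth: dict[str, dict] = {}
    with_data: list[tuple[PregnancySpec, int]] = []
    for spec, flags, child in zip(specs, gen_flags, child_seeds):
        if flags.get("no_data"):
            continue
        series, t = _simulate_one(
            spec,
            cfg,
            child,
            drop_window=flags.get("drop_window"),
            drop_keep_frac=flags.get("drop_keep_frac", 0.15),
            no_preonset=flags.get("no_preonset", False),
        )
        daily_frames.append(_daily_long(spec, series))
        truth[spec.pregnancy_id] = t
        with_data.append((spec, child))

    daily = (
        pd.concat(daily_frames, ignore_index=True)
        if daily_frames
        else pd.DataFrame(columns=["participant_id", "pregnancy_id", "date", "series", "value"])
    )
    survey = _survey_frame(specs)

    samples = sleep = None
    if minute_pregnancies > 0 and with_data:
        sample_parts, sleep_parts = [], []
        for spec, child in with_data[:minute_pregnancies]:
            sub = daily[daily["pregnancy_id"] == spec.pregnancy_id]
            wide = (
                sub.pivot_table(index="date", columns="series", values="value")
                .reindex(columns=list(SERIES_KEYS))
                .dropna()
            )
            wide.index = ((wide.index - spec.dkp).days).astype(int)
            s_df, sl_df = simulate_minute_stream(wide, spec, cfg, child + 1)
            sample_parts.append(s_df)
            sleep_parts.append(sl_df)
        samples = pd.concat(sample_parts, ignore_index=True)
        sleep = pd.concat(sleep_parts, ignore_index=True)

    return SyntheticCohort(survey=survey, daily=daily, truth=truth, samples=samples, sleep=sleep)


def _random_specs(cfg: SimulationConfig, seed: int):
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    base = pd.Timestamp("2020-06-01")
    specs: list[PregnancySpec] = []
    flags: list[dict] = []
    for i in range(cfg.n_full_term):
        dkp = base + pd.Timedelta(days=int(rng.integers(0, 120)))
        gest = int(rng.integers(cfg.gestation_days_range[0], cfg.gestation_days_range[1] + 1))
        dps = dkp + pd.Timedelta(days=gest + CONCEPTION_OFFSET)
        specs.append(
            PregnancySpec(
                participant_id=f"P{i:04d}",
                pregnancy_id=f"G{i:04d}",
                age_bin=_sample_age_bin(rng, cfg),
                dkp=dkp,
                dps=dps,
                outcome="full_term",
                high_risk=bool(rng.random() < 0.17),
            )
        )
        flags.append({})
    for j in range(cfg.n_efl):
        i = cfg.n_full_term + j
        dkp = base + pd.Timedelta(days=int(rng.integers(0, 120)))
        loss = int(rng.integers(cfg.efl_loss_day_range[0], cfg.efl_loss_day_range[1] + 1))
        specs.append(
            PregnancySpec(
                participant_id=f"P{i:04d}",
                pregnancy_id=f"G{i:04d}",
                age_bin=_sample_age_bin(rng, cfg),
                dkp=dkp,
                dps=dkp + pd.Timedelta(days=loss),
                outcome="efl_miscarriage",
                high_risk=bool(rng.random() < 0.3),
            )
        )
        flags.append({})
    return specs, flags


def _fixture_specs(seed: int):
    """Deterministic survey bookkeeping matching the study's subject counts."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1C5]))
    base = pd.Timestamp("2020-06-01")
    specs: list[PregnancySpec] = []
    flags: list[dict] = []
    pid = gid = 0

    def next_ids(new_participant: bool = True):
        nonlocal pid, gid
        if new_participant:
            pid += 1
        gid += 1
        return f"P{pid:04d}", f"G{gid:04d}"

    def dkp_for(i: int) -> pd.Timestamp:
        return base + pd.Timedelta(days=int(i % 180))

    # --- partner reports and out-of-window pregnancies (survey only) ---
    for i in range(FIXTURE_COUNTS["partner_report"]):
        p, g = next_ids()
        specs.append(
            PregnancySpec(p, g, "30-34", dkp_for(i), dkp_for(i) + pd.Timedelta(days=250),
                          "partner_report")
        )
        flags.append({"no_data": True})
    for i in range(FIXTURE_COUNTS["out_of_window"]):
        p, g = next_ids()
        dkp = pd.Timestamp("2017-01-01") + pd.Timedelta(days=int(i % 365))
        specs.append(PregnancySpec(p, g, "30-34", dkp, dkp + pd.Timedelta(days=231), "full_term"))
        flags.append({"no_data": True})

    # --- delivered arm: 224 pregnancies, 97 survive the filters ---
    # Included full-term: ages and high-risk flags follow the demographics
    # table; one participant contributes two pregnancies.
    ft_bins: list[tuple[str, bool]] = []
    for age_bin, (n_all, n_hr, _, _) in FIXTURE_AGE_TABLE.items():
        ft_bins += [(age_bin, k < n_hr) for k in range(n_all)]
    assert len(ft_bins) == 97
    repeat_participant = None
    for i, (age_bin, hr) in enumerate(ft_bins):
        reuse = i == 96  # final pregnancy reuses the first participant
        if reuse:
            p, g = repeat_participant, None
            _, g = next_ids(new_participant=False)
        else:
            p, g = next_ids()
            if i == 0:
                repeat_participant = p
        dkp = dkp_for(i)
        gest = 259 + int(rng.integers(0, 29))
        specs.append(
            PregnancySpec(p, g, age_bin, dkp, dkp + pd.Timedelta(days=gest + CONCEPTION_OFFSET),
                          "full_term", high_risk=hr)
        )
        flags.append({})
    # 47 sparse in one trimester (trimester 2 data mostly missing).
    for i in range(FIXTURE_COUNTS["delivered_sparse_trimester"]):
        p, g = next_ids()
        dkp = dkp_for(i)
        specs.append(PregnancySpec(p, g, "30-34", dkp, dkp + pd.Timedelta(days=235), "full_term"))
        flags.append({"drop_window": (63, 154)})
    # 76 excluded for sparseness around onset/end (explicitly labelled).
    for i in range(FIXTURE_COUNTS["delivered_sparse_other"]):
        p, g = next_ids()
        dkp = dkp_for(i)
        specs.append(
            PregnancySpec(p, g, "35-39", dkp, dkp + pd.Timedelta(days=240), "full_term",
                          exclude_hint="sparse_other")
        )
        flags.append({})
    # 4 preterm deliveries (< 37 weeks gestation).
    for i in range(FIXTURE_COUNTS["delivered_preterm"]):
        p, g = next_ids()
        dkp = dkp_for(i)
        gest = 240 + 4 * i  # 240..252 days, all < 259
        specs.append(
            PregnancySpec(p, g, "30-34", dkp, dkp + pd.Timedelta(days=gest + CONCEPTION_OFFSET),
                          "preterm")
        )
        flags.append({})

    # --- EFL arm: 34 reported, 23 survive the filters ---
    efl_bins: list[tuple[str, bool]] = []
    for age_bin, (_, _, n_all, n_hr) in FIXTURE_AGE_TABLE.items():
        efl_bins += [(age_bin, k < n_hr) for k in range(n_all)]
    assert len(efl_bins) == 23
    efl_loss_days = [8, 12, 18, 25, 30, 36, 45, 52, 55, 21, 38, 48, 10, 26, 41, 57, 15,
                     33, 50, 44, 28, 35, 58]
    # Three participants contribute two EFLs each (20 individuals, 23 EFLs).
    efl_participants: list[str] = []
    for i, (age_bin, hr) in enumerate(efl_bins):
        if i >= 20:  # reuse the first three EFL participants
            p = efl_participants[i - 20]
            _, g = next_ids(new_participant=False)
        else:
            p, g = next_ids()
            efl_participants.append(p)
        dkp = dkp_for(i)
        specs.append(
            PregnancySpec(p, g, age_bin, dkp, dkp + pd.Timedelta(days=efl_loss_days[i]),
                          "efl_miscarriage", high_risk=hr)
        )
        # The first included EFL lacks all pre-onset data; it survives the
        # cohort filters but is unusable for z-scored analyses.
        flags.append({"no_preonset": i == 0})
    for i in range(FIXTURE_COUNTS["efl_failure_to_implant"]):
        p, g = next_ids()
        dkp = dkp_for(i)
        specs.append(
            PregnancySpec(p, g, "35-39", dkp, dkp + pd.Timedelta(days=14),
                          "efl_failure_to_implant")
        )
        flags.append({})
    for i in range(FIXTURE_COUNTS["efl_low_first_trimester"]):
        p, g = next_ids()
        dkp = dkp_for(i)
        specs.append(
            PregnancySpec(p, g, "30-34", dkp, dkp + pd.Timedelta(days=30), "efl_miscarriage")
        )
        flags.append({"drop_window": (-28, 63), "drop_keep_frac": 0.1})
    for i in range(FIXTURE_COUNTS["efl_low_prior_completeness"]):
        p, g = next_ids()
        dkp = dkp_for(i)
        specs.append(
            PregnancySpec(p, g, "35-39", dkp, dkp + pd.Timedelta(days=40), "efl_miscarriage",
                          exclude_hint="low_prior_completeness")
        )
        flags.append({})
    return specs, flags


def fixture_config(**overrides) -> SimulationConfig:
    """Default configuration for fixture-mode cohorts."""
    return SimulationConfig(**overrides)
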