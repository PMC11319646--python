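"""Configuration objects shared across the pipeline.

All analysis stages are parameterised through small frozen-ish dataclasses
that validate themselves on construction.  Defaults encode the study
conditions: a 28-day pre-conception cycle, the 20:00-08:00 nightly window,
the two-pass per-participant quantile filters, the 0.5 MET wear gate, the
trimester day grid anchored at the date the pregnancy became known (DKP),
and the -60..-30 day pre-pregnancy baseline used for z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

#: The six daily analysis series the study tracks, keyed by a short name.
#: Each maps to a (modality, window, statistic) triple of the daily
#: aggregate table produced by :mod:`gestwear.preprocess`.
SERIES_KEYS = ("temp_peak", "temp_trough", "met_peak", "hr_peak", "hrv_peak", "rr_peak")

SERIES_TO_AGG: Mapping[str, tuple[str, str, str]] = {
    "temp_peak": ("temperature", "nightly", "peak"),
    "temp_trough": ("temperature", "nightly", "trough"),
    "met_peak": ("met", "h24", "peak"),
    "hr_peak": ("hr", "nightly", "peak"),
    "hrv_peak": ("hrv", "nightly", "peak"),
    "rr_peak": ("rr", "nightly", "peak"),
}

#: Units for each analysis series (temperature degC, HR bpm, HRV rmssd ms,
#: RR respirations/min, MET dimensionless activity units).
SERIES_UNITS = {
    "temp_peak": "degC",
    "temp_trough": "degC",
    "met_peak": "MET",
    "hr_peak": "bpm",
    "hrv_peak": "ms",
    "rr_peak": "rpm",
}

#: Outcome labels a survey row may carry.
OUTCOMES = (
    "full_term",
    "preterm",
    "efl_miscarriage",
    "efl_ectopic",
    "efl_chemical",
    "efl_termination",
    "efl_failure_to_implant",
    "partner_report",
    "out_of_window",
)

EFL_OUTCOMES = (
    "efl_miscarriage",
    "efl_ectopic",
    "efl_chemical",
    "efl_termination",
    "efl_failure_to_implant",
)

#: Survey age bins; the advanced-maternal-age split maps the first three to
#: "<35" and the last three to ">=35".
AGE_BINS = ("20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
AGE_BINS_UNDER_35 = ("20-24", "25-29", "30-34")


def _default_baselines() -> dict[str, float]:
    # Population-typical nightly values: distal-temperature nightly peak /
    # trough, 24 h peak activity, nightly peak HR / HRV / RR.
    return {
        "temp_peak": 36.3,
        "temp_trough": 31.0,
        "met_peak": 2.2,
        "hr_peak": 67.0,
        "hrv_peak": 68.0,
        "rr_peak": 17.6,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "temp_peak": 0.1,
        "temp_trough": 0.3,
        "met_peak": 0.3,
        "hr_peak": 2.0,
        "hrv_peak": 6.0,
        "rr_peak": 0.5,
    }


def _default_between_subject_sd() -> dict[str, float]:
    return {
        "temp_peak": 0.15,
        "temp_trough": 0.8,
        "met_peak": 0.4,
        "hr_peak": 5.0,
        "hrv_peak": 15.0,
        "rr_peak": 1.0,
    }


def _default_age_bin_probs() -> tuple[tuple[str, float], ...]:
    return (
        ("20-24", 0.02),
        ("25-29", 0.13),
        ("30-34", 0.36),
        ("35-39", 0.30),
        ("40-44", 0.16),
        ("45-49", 0.03),
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic wearable-pregnancy cohort generator."""

    n_full_term: int = 50
    n_efl: int = 10
    age_bins: tuple[tuple[str, float], ...] = field(default_factory=_default_age_bin_probs)
    baselines: dict[str, float] = field(default_factory=_default_baselines)
    cycle_length_days: int = 28
    luteal_amplitude: float = 0.3  # degC rise of the luteal-phase plateau
    conception_rise: float = 0.2  # degC by which the plateau exceeds the cycle peak
    gestation_days_range: tuple[int, int] = (259, 287)  # full term >= 37 weeks
    efl_loss_day_range: tuple[int, int] = (6, 58)  # days post-DKP
    efl_slope_intercept: float = 0.25  # decline rate for a day-0 loss (z/day by default)
    efl_slope_per_day: float = 0.003  # decline shrinks by this per loss day
    efl_slope_units: str = "z"  # "z": scaled by the baseline-window SD; or "degC"
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    between_subject_sd: dict[str, float] = field(default_factory=_default_between_subject_sd)
    missing_day_rate: float = 0.15
    nonwear_rate: float = 0.02  # expected fraction of minutes inside non-wear blocks
    pre_days: int = 91  # simulated days before DKP
    postpartum_days: int = 91  # simulated days after DPS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_full_term < 0 or self.n_efl < 0:
            raise ValueError("cohort sizes must be non-negative")
        for rate_name in ("missing_day_rate", "nonwear_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must lie in [0, 1], got {rate}")
        if self.cycle_length_days < 21:
            raise ValueError("cycle_length_days must be >= 21")
        lo, hi = self.gestation_days_range
        if lo < 259 or hi < lo:
            raise ValueError("full-term gestation bounds must satisfy 259 <= lo <= hi")
        lo, hi = self.efl_loss_day_range
        if not (0 < lo <= hi < 91):
            raise ValueError("efl_loss_day_range must lie inside the first trimester (0, 91)")
        if self.efl_slope_units not in ("z", "degC"):
            raise ValueError("efl_slope_units must be 'z' or 'degC'")
        if self.luteal_amplitude < 0 or self.conception_rise < 0:
            raise ValueError("amplitudes must be >= 0")
        probs = [p for _, p in self.age_bins]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("age bin probabilities must be non-negative and sum to 1")
        for key in SERIES_KEYS:
            if key not in self.baselines:
                raise ValueError(f"missing baseline for series {key!r}")

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class PreprocessConfig:
    """Sample-cleaning parameters for the raw-stream preprocessing pipeline."""

    first_pass_quantiles: tuple[float, float] = (0.05, 0.95)
    second_pass_quantiles: tuple[float, float] = (0.02, 0.98)
    met_gate: float = 0.5  # samples paired with MET strictly below this are dropped
    met_pair_tolerance_s: float = 60.0  # nearest-in-time pairing window
    nightly_window: tuple[int, int] = (20, 8)  # [20:00, 08:00) local clock hours
    peak_band: tuple[float, float] = (0.90, 0.95)
    trough_band: tuple[float, float] = (0.05, 0.10)
    peak_definition: str = "band_mean"  # or "endpoint_mean"

    def __post_init__(self) -> None:
        for lo, hi in (
            self.first_pass_quantiles,
            self.second_pass_quantiles,
            self.peak_band,
            self.trough_band,
        ):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"quantile pair must satisfy 0 <= low < high <= 1, got ({lo}, {hi})")
        if self.peak_definition not in ("band_mean", "endpoint_mean"):
            raise ValueError("peak_definition must be 'band_mean' or 'endpoint_mean'")


#: Half-open trimester windows in days relative to DKP (day 0).  Trimester 1
#: starts 28 days before DKP (conception); windows partition [-91, 343).
TRIMESTER_WINDOWS: Mapping[int, tuple[int, int]] = {
    -1: (-91, -28),
    1: (-28, 63),
    2: (63, 154),
    3: (154, 252),
    4: (252, 343),
}


@dataclass
class AlignmentScheme:
    """Day-grid conventions: anchors, trimester windows, baseline window."""

    anchor: str = "dkp"  # or "dps"
    trimester_windows: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: dict(TRIMESTER_WINDOWS)
    )
    baseline_window: tuple[int, int] = (-60, -30)  # half-open, days relative to DKP
    completeness_threshold: float = 0.40
    min_baseline_days: int = 5

    def __post_init__(self) -> None:
        if self.anchor not in ("dkp", "dps"):
            raise ValueError("anchor must be 'dkp' or 'dps'")
        bounds = sorted(self.trimester_windows.values())
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            if a1 != b0:
                raise ValueError("trimester windows must be contiguous and disjoint")
        if not self.baseline_window[0] < self.baseline_window[1] <= self.trimester_windows[1][0]:
            raise ValueError("baseline window must precede trimester 1")

    def window_length(self, trimester: int) -> int:
        lo, hi = self.trimester_windows[trimester]
        return hi - lo


@dataclass
class GeeSpec:
    """Design of the time-matched early-fetal-loss GEE."""

    k_controls: int = 5
    length_thresholds: tuple[int, ...] = (14, 28, 40, 60)
    cov_struct: str = "independence"  # or "exchangeable"
    smoothing_days: int = 3
    post_days: int = 7  # days following DPS entering the model (offsets 0..6)
    min_window_days: int = 5  # control coverage required over the matched window

    def __post_init__(self) -> None:
        if self.k_controls < 0:
            raise ValueError("k_controls must be >= 0")
        if tuple(sorted(self.length_thresholds)) != tuple(self.length_thresholds):
            raise ValueError("length_thresholds must be sorted ascending")
        if self.cov_struct not in ("independence", "exchangeable"):
            raise ValueError("cov_struct must be 'independence' or 'exchangeable'")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one YAML file drives a run)."""

    out_dir: str = "gestwear_run"
    seed: int = 0
    fixture: bool = False
    minute_stream_pregnancies: int = 0
    output_format: str = "csv"  # or "parquet"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "preprocess": True,
            "cohort": True,
            "profiles": True,
            "distance": True,
            "efl": True,
        }
    )
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alignment: AlignmentScheme = field(default_factory=AlignmentScheme)
    gee: GeeSpec = field(default_factory=GeeSpec)

    def __post_init__(self) -> None:
        if self.output_format not in ("csv", "parquet"):
            raise ValueError("output_format must be 'csv' or 'parquet'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("simulation", SimulationConfig),
            ("preprocess", PreprocessConfig),
            ("alignment", AlignmentScheme),
            ("gee", GeeSpec),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                # YAML lists come back as lists; dataclass fields expect tuples
                for name, value in section.items():
                    if isinstance(value, list):
                        section[name] = tuple(
                            tuple(v) if isinstance(v, list) else v for v in value
                        )
                kwargs[key] = sub(**section)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
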