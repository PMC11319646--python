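"""Raw sample-stream cleaning and daily aggregation.

The pipeline mirrors how minute-resolution ring data are reduced to daily
statistics: timestamps are normalised to naive local time and
de-duplicated, a first per-participant 5-95% quantile filter removes
gross outliers, samples whose nearest activity (MET) reading is below
0.5 MET are dropped as non-wear artefacts, samples are annotated
awake/asleep from per-night sleep summaries, a second 2-98% per
participant-and-modality filter is applied, and finally per-day
mean/median/peak/trough statistics are computed over both the 24 h and
the fixed 20:00-08:00 nightly window.

"Peak" is the mean of the sample values whose midpoint rank (i - 0.5)/n
falls in the 0.90-0.95 band ("trough": 0.05-0.10); when the band is empty
(tiny n) the interpolated mid-band quantile is used instead.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PreprocessConfig

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["participant_id", "pregnancy_id", "timestamp_local", "modality", "value"]


def load_and_normalize(paths: list[str | Path] | pd.DataFrame) -> pd.DataFrame:
    """Read sample tables, coerce timestamps, drop duplicates, sort.

    Accepts CSV/Parquet paths or an already-loaded DataFrame.  Rows whose
    timestamps cannot be parsed are rejected (row-level); more than 10%
    rejected is treated as a corrupt input and raises.
    """
    if isinstance(paths, pd.DataFrame):
        frames = [paths.copy()]
    else:
        frames = []
        for p in paths:
            p = Path(p)
            if p.suffix == ".parquet":
                frames.append(pd.read_parquet(p))
            else:
                frames.append(pd.read_csv(p))
    df = pd.concat(frames, ignore_index=True)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing columns: {missing}")

    n_in = len(df)
    stamps = pd.to_datetime(df["timestamp_local"], errors="coerce")
    if getattr(stamps.dt, "tz", None) is not None:
        stamps = stamps.dt.tz_localize(None)
    bad = stamps.isna() | ~np.isfinite(df["value"].to_numpy(dtype=float))
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("rejected %d/%d unparseable or non-finite sample rows", n_bad, n_in)
        if n_in and n_bad / n_in > 0.10:
            raise ValueError(f"{n_bad}/{n_in} sample rows rejected (> 10%)")
    df = df.loc[~bad].copy()
    df["timestamp_local"] = stamps.loc[~bad]
    df = df.drop_duplicates(subset=["participant_id", "modality", "timestamp_local"], keep="first")
    df = df.sort_values(["participant_id", "timestamp_local"], kind="mergesort")
    return df.reset_index(drop=True)


def select_longest_sleep(sleep: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per (participant, date): the longest sleep, earliest-start tie-break."""
    df = sleep.copy()
    df["sleep_start"] = pd.to_datetime(df["sleep_start"])
    df["sleep_end"] = pd.to_datetime(df["sleep_end"])
    df = df.sort_values(
        ["participant_id", "date", "duration_s", "sleep_start"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return df.drop_duplicates(subset=["participant_id", "date"], keep="first").reset_index(drop=True)


def quantile_filter(
    samples: pd.DataFrame,
    low: float,
    high: float,
    scope: str = "per_participant",
) -> pd.DataFrame:
    """Drop values strictly outside the interpolated [Q(low), Q(high)] band.

    Quantiles are computed by linear interpolation of order statistics.
    Modality streams are always filtered separately (they live on
    incommensurable scales); ``scope`` records whether the pass is the
    participant-level first filter or the per-participant-and-modality
    second filter, and additionally splits by pregnancy in the latter
    case when a pregnancy column is present.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"need 0 <= low < high <= 1, got ({low}, {high})")
    if low == 0.0 and high == 1.0:
        return samples.copy()
    keys = {
        "per_participant": ["participant_id", "modality"],
        "per_participant_modality": ["participant_id", "pregnancy_id", "modality"]
        if "pregnancy_id" in samples.columns
        else ["participant_id", "modality"],
    }[scope]
    df = samples.copy()
    grouped = df.groupby(keys, observed=True)["value"]
    lo = grouped.transform(lambda v: np.quantile(v, low))
    hi = grouped.transform(lambda v: np.quantile(v, high))
    return df.loc[(df["value"] >= lo) & (df["value"] <= hi)].reset_index(drop=True)


def met_gate_filter(
    samples: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Drop non-MET samples whose nearest-in-time MET reading is below the gate.

    Pairing is nearest within +-``met_pair_tolerance_s`` per participant;
    samples with no MET reading inside the tolerance are retained, as are
    all MET samples.  The comparison is strict (exactly 0.5 MET survives).
    """
    cfg = cfg or PreprocessConfig()
    met = samples[samples["modality"] == "met"]
    if met.empty:
        log.warning("no MET stream present; wear gate is vacuous")
        return samples.copy()
    others = samples[samples["modality"] != "met"]
    if others.empty:
        return samples.copy()

    met_sorted = met.sort_values("timestamp_local")[
        ["participant_id", "timestamp_local", "value"]
    ].rename(columns={"value": "met_value"})
    others_sorted = others.sort_values("timestamp_local").reset_index()
    paired = pd.merge_asof(
        others_sorted,
        met_sorted,
        on="timestamp_local",
        by="participant_id",
        direction="nearest",
        tolerance=pd.Timedelta(seconds=cfg.met_pair_tolerance_s),
    )
    drop = paired["met_value"].notna() & (paired["met_value"] < cfg.met_gate)
    kept_idx = paired.loc[~drop, "index"]
    out = pd.concat([met, others.loc[others.index.isin(kept_idx)]])
    return out.sort_values(["participant_id", "timestamp_local"], kind="mergesort").reset_index(
        drop=True
    )


def annotate_sleep(samples: pd.DataFrame, sleep: pd.DataFrame) -> pd.DataFrame:
    """Add an ``asleep`` flag: True iff the timestamp lies in [start, end) of
    the participant's selected sleep interval for some night."""
    df = samples.copy()
    df["asleep"] = False
    if sleep.empty:
        return df
    for pid, nights in sleep.groupby("participant_id"):
        mask = df["participant_id"] == pid
        if not mask.any():
            continue
        stamps = df.loc[mask, "timestamp_local"]
        asleep = np.zeros(len(stamps), dtype=bool)
        for _, night in nights.iterrows():
            asleep |= (
                (stamps >= night["sleep_start"]) & (stamps < night["sleep_end"])
            ).to_numpy()
        df.loc[mask, "asleep"] = asleep
    return df


def _band_mean(values: np.ndarray, lo: float, hi: float, definition: str = "band_mean") -> float:
    """Mean of values whose midpoint rank lies in [lo, hi]; interpolated
    mid-band quantile when the band is empty."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        return np.nan
    if definition == "endpoint_mean":
        return float((np.quantile(v, lo) + np.quantile(v, hi)) / 2.0)
    ranks = (np.arange(1, n + 1) - 0.5) / n
    sel = (ranks >= lo) & (ranks <= hi)
    if sel.any():
        return float(v[sel].mean())
    return float(np.quantile(v, (lo + hi) / 2.0))


def _assign_window_date(stamps: pd.Series, window: str, cfg: PreprocessConfig) -> pd.Series:
    if window == "h24":
        return stamps.dt.normalize()
    start_h, end_h = cfg.nightly_window
    hours = stamps.dt.hour
    in_night = (hours >= start_h) | (hours < end_h)
    date = stamps.dt.normalize().where(hours >= start_h, stamps.dt.normalize() - pd.Timedelta(days=1))
    return date.where(in_night, pd.NaT)


def daily_aggregate(
    samples: pd.DataFrame, window: str, cfg: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Per (participant, pregnancy, date, modality) daily statistics.

    ``window`` is ``"h24"`` (calendar day) or ``"nightly"`` (the half-open
    [20:00 of date, 08:00 of date+1) clock window).  Emits mean, median,
    peak, trough, and n_samples; keys with no samples emit no row.
    """
    cfg = cfg or PreprocessConfig()
    if window not in ("h24", "nightly"):
        raise ValueError("window must be 'h24' or 'nightly'")
    df = samples.copy()
    df["date"] = _assign_window_date(df["timestamp_local"], window, cfg)
    df = df.dropna(subset=["date"])
    if df.empty:
        return pd.DataFrame(
            columns=[
                "participant_id", "pregnancy_id", "date", "window", "modality",
                "mean", "median", "peak", "trough", "n_samples",
            ]
        )

    def agg(group: pd.Series) -> pd.Series:
        v = group.to_numpy(dtype=float)
        return pd.Series(
            {
                "mean": v.mean(),
                "median": float(np.median(v)),
                "peak": _band_mean(v, *cfg.peak_band, cfg.peak_definition),
                "trough": _band_mean(v, *cfg.trough_band, cfg.peak_definition),
                "n_samples": v.size,
            }
        )

    keys = ["participant_id", "pregnancy_id", "date", "modality"]
    out = df.groupby(keys, observed=True)["value"].apply(agg).unstack().reset_index()
    out["n_samples"] = out["n_samples"].astype(int)
    out.insert(2, "window", window)
    cols = ["participant_id", "pregnancy_id", "date", "window", "modality",
            "mean", "median", "peak", "trough", "n_samples"]
    return out[cols]


def preprocess_pipeline(
    samples: pd.DataFrame,
    sleep: pd.DataFrame | None = None,
    cfg: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Full cleaning pipeline: load -> 5-95% filter (per participant) ->
    MET wear gate -> sleep annotation -> 2-98% filter (per participant and
    modality) -> daily aggregates over both windows."""
    cfg = cfg or PreprocessConfig()
    df = load_and_normalize(samples)
    df = quantile_filter(df, *cfg.first_pass_quantiles, scope="per_participant")
    df = met_gate_filter(df, cfg)
    if sleep is not None and not sleep.empty:
        df = annotate_sleep(df, select_longest_sleep(sleep))
    df = quantile_filter(df, *cfg.second_pass_quantiles, scope="per_participant_modality")
    parts = [daily_aggregate(df, w, cfg) for w in ("h24", "nightly")]
    return pd.concat(parts, ignore_index=True)


def analysis_series(daily_aggregates: pd.DataFrame) -> pd.DataFrame:
    """Project DailyAggregate rows onto the six analysis series
    (long format: participant_id, pregnancy_id, date, series, value)."""
    from .config import SERIES_TO_AGG

    parts = []
    for key, (modality, window, stat) in SERIES_TO_AGG.items():
        sub = daily_aggregates[
            (daily_aggregates["modality"] == modality)
            & (daily_aggregates["window"] == window)
        ]
        if sub.empty:
            continue
        part = sub[["participant_id", "pregnancy_id", "date", stat]].rename(
            columns={stat: "value"}
        )
        part["series"] = key
        parts.append(part[["participant_id", "pregnancy_id", "date", "series", "value"]])
    if not parts:
        return pd.DataFrame(columns=["participant_id", "pregnancy_id", "date", "series", "value"])
    return pd.concat(parts, ignore_index=True)
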