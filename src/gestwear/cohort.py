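"""Survey parsing, outcome classification, eligibility filtering, alignment.

Pregnancies are aligned on an integer day grid where day 0 is the anchor
date (DKP for trajectory analyses, DPS for peridelivery and loss
analyses).  Trimester windows are half-open and partition [-91, 343):
t-1 = [-91, -28), t1 = [-28, 63), t2 = [63, 154), t3 = [154, 252),
t4 = [252, 343).  Eligibility requires daily temperature coverage of at
least 40% of days in each of trimesters 1-3 (full-term arm) or in the
first trimester (loss arm); gestation length is (DPS - DKP) + 28 days,
treating conception as 28 days before DKP, and full term is >= 259 days
(37 weeks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AlignmentScheme, EFL_OUTCOMES
from .simulate import CONCEPTION_OFFSET, DATA_WINDOW

log = logging.getLogger(__name__)

EXCLUSION_REASONS = (
    "partner_report",
    "out_of_window",
    "sparse_trimester",
    "sparse_other",
    "preterm",
    "failure_to_implant",
    "low_first_trimester",
    "low_prior_completeness",
    "none",
)


@dataclass
class CohortResult:
    """Classified survey records plus the exclusion ledger."""

    records: pd.DataFrame  # survey columns + gestation_days, completeness, included, exclusion_reason
    ledger: dict[str, int]

    @property
    def included(self) -> pd.DataFrame:
        return self.records[self.records["included"]]

    @property
    def full_term(self) -> pd.DataFrame:
        inc = self.included
        return inc[inc["arm"] == "full_term"]

    @property
    def efl(self) -> pd.DataFrame:
        inc = self.included
        return inc[inc["arm"] == "efl"]


def gestation_days(dkp: pd.Timestamp, dps: pd.Timestamp) -> int:
    """Gestation length in days, counting from conception = DKP - 28."""
    return int((pd.Timestamp(dps) - pd.Timestamp(dkp)).days) - CONCEPTION_OFFSET


def classify_outcome(record: pd.Series | dict) -> str:
    """Outcome category for one survey record.

    Reported EFL subtypes and partner/out-of-window labels pass through;
    delivered pregnancies are full term iff gestation >= 259 days, else
    preterm.  Missing anchor dates raise.
    """
    rec = dict(record)
    outcome = rec.get("outcome", "")
    if outcome in EFL_OUTCOMES or outcome in ("partner_report", "out_of_window"):
        return outcome
    if pd.isna(rec.get("dkp")) or pd.isna(rec.get("dps")):
        raise ValueError("record lacks anchor dates (dkp/dps)")
    return "full_term" if gestation_days(rec["dkp"], rec["dps"]) >= 259 else "preterm"


def align_days(dates: pd.Series, anchor: pd.Timestamp) -> pd.Series:
    """Integer day index of calendar dates relative to an anchor date."""
    return (pd.to_datetime(dates) - pd.Timestamp(anchor)).dt.days


def align_cohort(
    daily: pd.DataFrame, survey: pd.DataFrame, anchor: str = "dkp"
) -> pd.DataFrame:
    """Add a ``day`` column (relative to each pregnancy's anchor date) to a
    long daily-series table."""
    if anchor not in ("dkp", "dps"):
        raise ValueError("anchor must be 'dkp' or 'dps'")
    anchors = survey.set_index("pregnancy_id")[anchor]
    if daily["pregnancy_id"].map(anchors).isna().any():
        missing = set(daily["pregnancy_id"]) - set(anchors.index)
        raise ValueError(f"anchor date missing for pregnancies: {sorted(missing)[:5]}")
    out = daily.copy()
    anchor_dates = pd.to_datetime(out["pregnancy_id"].map(anchors))
    out["day"] = (pd.to_datetime(out["date"]) - anchor_dates).dt.days.astype(int)
    return out


def completeness(
    aligned_temp_days: pd.Series | np.ndarray,
    scheme: AlignmentScheme,
    trimesters: tuple[int, ...] = (1, 2, 3),
) -> dict[int, float]:
    """Fraction of days with a temperature aggregate in each trimester window."""
    days = np.unique(np.asarray(aligned_temp_days, dtype=int))
    out = {}
    for t in trimesters:
        lo, hi = scheme.trimester_windows[t]
        out[t] = float(((days >= lo) & (days < hi)).sum()) / (hi - lo)
    return out


def _in_window(dkp: pd.Timestamp, dps: pd.Timestamp) -> bool:
    start, end = DATA_WINDOW
    return (pd.Timestamp(dkp) + pd.Timedelta(days=CONCEPTION_OFFSET) >= start) and (
        pd.Timestamp(dps) <= end
    )


def build_cohort(
    survey: pd.DataFrame,
    daily: pd.DataFrame,
    scheme: AlignmentScheme | None = None,
) -> CohortResult:
    """Apply the eligibility filters in the study's narrative order.

    Both arms: partner reports and pregnancies outside the data-collection
    window are removed first.  Delivered arm: trimester temperature
    completeness (>= 40% of days in each of t1-t3), explicitly labelled
    onset/offset sparseness, then the preterm exclusion.  Loss arm:
    failure-to-implant, first-trimester completeness, then explicitly
    labelled low prior-to-pregnancy completeness.  Each excluded pregnancy
    receives exactly one reason; two pregnancies from one participant are
    retained as independent units.
    """
    scheme = scheme or AlignmentScheme()
    survey = survey.copy()
    survey["dkp"] = pd.to_datetime(survey["dkp"])
    survey["dps"] = pd.to_datetime(survey["dps"])
    if "exclude_hint" not in survey.columns:
        survey["exclude_hint"] = "none"

    orphans = set(daily["pregnancy_id"]) - set(survey["pregnancy_id"])
    if orphans:
        log.warning("daily data for %d pregnancies with no survey row; ignored", len(orphans))

    temp = daily[daily["series"] == "temp_peak"] if "series" in daily.columns else daily
    temp_days = {
        pid: align_days(sub["date"], survey.set_index("pregnancy_id").loc[pid, "dkp"])
        for pid, sub in temp.groupby("pregnancy_id")
        if pid in set(survey["pregnancy_id"])
    }

    rows = []
    for _, rec in survey.iterrows():
        pid = rec["pregnancy_id"]
        outcome = rec["outcome"]
        days = temp_days.get(pid, pd.Series([], dtype=int))
        fracs = completeness(days, scheme)
        gest = (
            gestation_days(rec["dkp"], rec["dps"])
            if pd.notna(rec["dkp"]) and pd.notna(rec["dps"])
            else np.nan
        )

        reason = "none"
        arm = ""
        if outcome == "partner_report":
            reason = "partner_report"
        elif outcome == "out_of_window" or not _in_window(rec["dkp"], rec["dps"]):
            reason = "out_of_window"
        elif outcome in EFL_OUTCOMES:
            arm = "efl"
            if outcome == "efl_failure_to_implant":
                reason = "failure_to_implant"
            elif fracs[1] < scheme.completeness_threshold:
                reason = "low_first_trimester"
            elif rec["exclude_hint"] == "low_prior_completeness":
                reason = "low_prior_completeness"
        else:
            arm = "full_term"
            if any(fracs[t] < scheme.completeness_threshold for t in (1, 2, 3)):
                reason = "sparse_trimester"
            elif rec["exclude_hint"] == "sparse_other":
                reason = "sparse_other"
            elif classify_outcome(rec) == "preterm":
                reason = "preterm"

        rows.append(
            {
                **rec.to_dict(),
                "gestation_days": gest,
                "t1_frac": fracs[1],
                "t2_frac": fracs[2],
                "t3_frac": fracs[3],
                "arm": arm,
                "included": reason == "none" and arm != "",
                "exclusion_reason": reason,
            }
        )

    records = pd.DataFrame(rows)
    if records.empty:
        return CohortResult(records=records, ledger={})
    ledger = (
        records.loc[records["exclusion_reason"] != "none", "exclusion_reason"]
        .value_counts()
        .to_dict()
    )
    return CohortResult(records=records, ledger=ledger)


def detect_cycle_trough(
    aligned_series: pd.Series,
    window: tuple[int, int] = (-45, 0),
    smooth_days: int = 5,
    min_pre_days: int = 35,
) -> dict | None:
    """Diagnostic: day of the most recent pre-DKP nightly-peak trough.

    Returns the argmin of a centred ``smooth_days``-day rolling mean over
    the given pre-DKP window, or None when fewer than ``min_pre_days``
    pre-DKP days are present.  Reported only as a consistency check of the
    DKP anchor (the trough is expected ~28 days before DKP, i.e. the start
    of the conception cycle); it never re-anchors anything.
    """
    s = aligned_series.dropna()
    pre = s[s.index < 0]
    if len(pre) < min_pre_days:
        return None
    lo, hi = window
    full = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1))
    smooth = full.rolling(smooth_days, center=True, min_periods=max(2, smooth_days // 2)).mean()
    win = smooth[(smooth.index >= lo) & (smooth.index < hi)].dropna()
    if win.empty:
        return None
    trough_day = int(win.idxmin())
    monotone = bool((win.diff().dropna() > 0).all())
    return {"trough_day": trough_day, "low_confidence": monotone or trough_day == win.index.min()}
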