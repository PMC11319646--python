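"""Cumulative multimodal Euclidean distance between pregnancy trajectories.

Each pregnancy-day is a 4-vector of z-scored daily values (nightly
temperature peak and trough, nightly peak HR and HRV); a day is usable
only when all four components are present.  A reference trajectory is the
per-day componentwise mean over a reference group (with a leave-one-out
variant when scoring members of the reference group itself).  The daily
Euclidean distance to the reference is accumulated from 4 weeks before
DKP through day 252 (40 weeks); days failing the completeness rule
contribute zero and carry the running total forward, so the cumulative
series is nondecreasing by construction.  Group endpoints are compared
with a tie-corrected Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: The four most complete analysis series entering the distance statistic.
POINT_SERIES = ("temp_peak", "temp_trough", "hr_peak", "hrv_peak")

#: Accumulation window: 4 weeks before DKP through 40 weeks of pregnancy.
DEFAULT_DAY_RANGE = (-28, 252)


def daily_points(z_aligned: pd.DataFrame, series: tuple[str, ...] = POINT_SERIES) -> pd.DataFrame:
    """Wide per-day 4-vectors per pregnancy; days missing any component drop.

    Input: long z-scored aligned table (pregnancy_id, day, series, value).
    Pregnancies missing an entire component series are excluded (logged).
    """
    sub = z_aligned[z_aligned["series"].isin(series)]
    have = sub.groupby("pregnancy_id")["series"].nunique()
    incomplete = have[have < len(series)].index
    if len(incomplete):
        log.info("excluding %d pregnancies missing a component series", len(incomplete))
        sub = sub[~sub["pregnancy_id"].isin(incomplete)]
    wide = sub.pivot_table(
        index=["pregnancy_id", "day"], columns="series", values="value", aggfunc="mean"
    ).reindex(columns=list(series))
    wide = wide.dropna(how="any").reset_index()
    wide.columns.name = None
    return wide


def reference_profile(
    points: pd.DataFrame,
    leave_out: str | None = None,
    series: tuple[str, ...] = POINT_SERIES,
) -> pd.DataFrame:
    """Per-day componentwise mean over a reference group.

    With ``leave_out`` the named pregnancy is excluded (the leave-one-out
    reference used when scoring members of the reference group); the group
    must then contain at least two pregnancies.  Days with no contributor
    are omitted.
    """
    pool = points
    if leave_out is not None:
        if points["pregnancy_id"].nunique() < 2:
            raise ValueError("leave-one-out reference needs a group of size >= 2")
        pool = points[points["pregnancy_id"] != leave_out]
    ref = pool.groupby("day")[list(series)].mean().dropna(how="any")
    return ref


def distance_series(
    points: pd.DataFrame,
    reference: pd.DataFrame,
    day_range: tuple[int, int] = DEFAULT_DAY_RANGE,
    series: tuple[str, ...] = POINT_SERIES,
) -> pd.DataFrame:
    """Daily Euclidean distance to the reference plus its running sum.

    Defined on every day of ``day_range`` (half-open on neither side:
    days day_range[0]..day_range[1] inclusive); days without a usable
    point or reference contribute zero distance.
    """
    if reference.empty:
        log.warning("empty reference; distance series is empty")
        return pd.DataFrame(columns=["day", "distance", "cumulative"])
    pts = points.set_index("day")[list(series)]
    days = np.arange(day_range[0], day_range[1] + 1)
    aligned_pts = pts.reindex(days)
    aligned_ref = reference.reindex(days)
    diff = aligned_pts.to_numpy(dtype=float) - aligned_ref.to_numpy(dtype=float)
    dist = np.sqrt(np.nansum(diff**2, axis=1))
    dist[np.isnan(diff).any(axis=1)] = 0.0
    out = pd.DataFrame({"day": days, "distance": dist})
    out["cumulative"] = out["distance"].cumsum()
    return out


def cohort_distances(
    points: pd.DataFrame,
    groups: pd.Series,
    reference_group: str = "<35",
    day_range: tuple[int, int] = DEFAULT_DAY_RANGE,
    series: tuple[str, ...] = POINT_SERIES,
) -> pd.DataFrame:
    """Distance series for every pregnancy against the reference group mean.

    Members of the reference group are scored against the leave-one-out
    reference; members of other groups against the full reference-group
    mean.  ``groups`` maps pregnancy_id -> group label.
    """
    ref_members = points[points["pregnancy_id"].map(groups) == reference_group]
    full_ref = reference_profile(ref_members, series=series)
    frames = []
    for pid, sub in points.groupby("pregnancy_id"):
        if groups.get(pid) == reference_group:
            ref = reference_profile(ref_members, leave_out=pid, series=series)
        else:
            ref = full_ref
        ds = distance_series(sub, ref, day_range=day_range, series=series)
        ds.insert(0, "pregnancy_id", pid)
        ds["group"] = groups.get(pid)
        frames.append(ds)
    return pd.concat(frames, ignore_index=True)


@dataclass
class KruskalResult:
    h_statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


def compare_final_distance(
    endpoints_by_group: dict[str, np.ndarray], method: str = "auto"
) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis test on per-group cumulative endpoints.

    The chi-square reference distribution is coarse for very small groups,
    so ``method="auto"`` switches to the exact permutation null (all group
    relabellings) when the pooled sample has at most 12 values; the
    asymptotic path is used otherwise (and for the cohort-scale age
    comparison in practice).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in endpoints_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("each group needs at least two members")
    values = list(groups.values())
    n_total = sum(v.size for v in values)
    try:
        h, p = stats.kruskal(*values)
    except ValueError:  # all values identical across groups
        h, p = 0.0, 1.0
    if not (np.isfinite(h) and np.isfinite(p)):  # degenerate all-tied input
        h, p = 0.0, 1.0
    use_exact = method == "exact" or (method == "auto" and n_total <= 12)
    if use_exact and len(values) == 2 and h > 0:
        p = _exact_kruskal_p(values[0], values[1], float(h))
    return KruskalResult(
        h_statistic=float(h), p_value=float(p), group_sizes=tuple(v.size for v in values)
    )


def _exact_kruskal_p(x: np.ndarray, y: np.ndarray, h_obs: float) -> float:
    """Exact two-group permutation p-value P(H >= observed H)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    count = total = 0
    for idx in combinations(range(n), nx):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        h_perm, _ = stats.kruskal(pooled[sel], pooled[~sel])
        total += 1
        if h_perm >= h_obs - 1e-12:
            count += 1
    return count / total


def final_endpoints(distances: pd.DataFrame, day: int = DEFAULT_DAY_RANGE[1]) -> dict[str, np.ndarray]:
    """Cumulative distance at the endpoint day, keyed by group label."""
    at_end = distances[distances["day"] == day]
    return {
        str(g): sub["cumulative"].to_numpy(dtype=float)
        for g, sub in at_end.groupby("group")
    }
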