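"""Baseline z-scoring, smoothing, population profiles, and rank tests.

Each pregnancy is normalised against its own pre-pregnancy state: the
mean and sample standard deviation of daily values over days -60..-30
relative to DKP define z = (x - mu) / sigma.  Population profiles report
the cross-pregnancy median, interpolated 10-90% quantile band, and a
seeded percentile-bootstrap 95% CI of the median per aligned day.
Per-trimester means are compared between adjacent trimesters with the
two-sided Mann-Whitney-Wilcoxon test under a Bonferroni correction for
the four comparisons; the same machinery drives the advanced-maternal-age
(< 35 vs >= 35 years) weekly and 4-week bin comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_BINS_UNDER_35, AlignmentScheme

log = logging.getLogger(__name__)

#: Annotation thresholds after Bonferroni correction for m = 4 comparisons
#: (the statannotations star convention with alpha scaled by 1/4).
ANNOTATION_THRESHOLDS = (
    ("****", 1e-4 / 4),
    ("***", 1e-3 / 4),
    ("**", 1e-2 / 4),
    ("*", 5e-2 / 4),
)


def annotate_p(p: float, m: int = 4) -> str:
    """Star annotation for a p-value under Bonferroni correction for m tests."""
    scale = m / 4.0  # thresholds above are pre-scaled for m = 4
    for stars, cut in ANNOTATION_THRESHOLDS:
        if p <= cut / scale:
            return stars
    return "ns"


@dataclass
class RankTestResult:
    comparison: str
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    annotation: str


# ---------------------------------------------------------------------------
# Baseline statistics and z-scoring


def baseline_stats(
    aligned: pd.DataFrame, scheme: AlignmentScheme | None = None
) -> pd.DataFrame:
    """Per (pregnancy, series) baseline mean/SD over the -60..-30 day window.

    A baseline is usable only with at least ``scheme.min_baseline_days``
    observed days and a strictly positive sample SD (ddof 1).
    """
    scheme = scheme or AlignmentScheme()
    lo, hi = scheme.baseline_window
    base = aligned[(aligned["day"] >= lo) & (aligned["day"] < hi)]
    grouped = base.groupby(["pregnancy_id", "series"], observed=True)["value"]
    out = grouped.agg(mu="mean", sigma=lambda v: v.std(ddof=1), n_days="count").reset_index()
    all_keys = aligned[["pregnancy_id", "series"]].drop_duplicates()
    out = all_keys.merge(out, on=["pregnancy_id", "series"], how="left")
    out["n_days"] = out["n_days"].fillna(0).astype(int)
    # an effectively-constant baseline (SD at float-noise level) is unusable
    sd_floor = 1e-9 * np.maximum(1.0, out["mu"].abs())
    out["usable"] = (out["n_days"] >= scheme.min_baseline_days) & (out["sigma"] > sd_floor)
    return out


def zscore(aligned: pd.DataFrame, stats_df: pd.DataFrame) -> pd.DataFrame:
    """z-transform aligned values against their pregnancy/series baseline.

    Rows whose baseline is unusable are dropped (logged); day indices are
    unchanged.
    """
    usable = stats_df[stats_df["usable"]]
    n_dropped = stats_df.shape[0] - usable.shape[0]
    if n_dropped:
        log.info("dropping %d pregnancy-series with unusable baselines", n_dropped)
    merged = aligned.merge(
        usable[["pregnancy_id", "series", "mu", "sigma"]],
        on=["pregnancy_id", "series"],
        how="inner",
    )
    merged["value"] = (merged["value"] - merged["mu"]) / merged["sigma"]
    return merged.drop(columns=["mu", "sigma"])


def zscore_series(series: pd.Series, mu: float, sigma: float) -> pd.Series:
    """z-transform a single day-indexed series; sigma must be positive."""
    if not sigma > 0:
        raise ValueError("baseline SD must be strictly positive")
    return (series - mu) / sigma


def rolling_mean(series: pd.Series, window_days: int) -> pd.Series:
    """Trailing mean over calendar days (not row positions), min 1 observation.

    The output is defined on exactly the input's day set; gaps inside the
    trailing window simply contribute fewer observations.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if series.empty or window_days == 1:
        return series.copy()
    idx = series.index.astype(int)
    full = series.copy()
    full.index = idx
    full = full.reindex(range(idx.min(), idx.max() + 1))
    smoothed = full.rolling(window_days, min_periods=1).mean()
    return smoothed.loc[idx]


# ---------------------------------------------------------------------------
# Population profiles


def population_profile(
    aligned: pd.DataFrame,
    quantiles: tuple[float, float] = (0.10, 0.90),
    n_boot: int = 1000,
    seed: int = 0,
    min_n_ci: int = 3,
) -> pd.DataFrame:
    """Per-day cohort median, quantile band, and bootstrap 95% CI of the median.

    Input is a long table with ``day`` and ``value`` columns (one row per
    pregnancy-day).  Days observed in fewer than ``min_n_ci`` pregnancies
    report a degenerate CI equal to the median.
    """
    if aligned.empty:
        raise ValueError("population_profile needs at least one series")
    qlo, qhi = quantiles
    rng = np.random.default_rng(seed)
    rows = []
    for day, grp in aligned.groupby("day"):
        v = grp["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        med = float(np.median(v))
        row = {
            "day": int(day),
            "n": int(v.size),
            "median": med,
            "q_lo": float(np.quantile(v, qlo)),
            "q_hi": float(np.quantile(v, qhi)),
        }
        if v.size >= min_n_ci:
            idx = rng.integers(0, v.size, size=(n_boot, v.size))
            boots = np.median(v[idx], axis=1)
            row["ci_lo"] = float(np.percentile(boots, 2.5))
            row["ci_hi"] = float(np.percentile(boots, 97.5))
        else:
            row["ci_lo"] = row["ci_hi"] = med
        rows.append(row)
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)


def trimester_means(
    aligned: pd.DataFrame, scheme: AlignmentScheme | None = None
) -> pd.DataFrame:
    """Per-pregnancy, per-series mean of daily values in each trimester window.

    Trimesters with no observed days are omitted for that pregnancy.
    """
    scheme = scheme or AlignmentScheme()
    rows = []
    for t, (lo, hi) in scheme.trimester_windows.items():
        sub = aligned[(aligned["day"] >= lo) & (aligned["day"] < hi)]
        if sub.empty:
            continue
        means = (
            sub.groupby(["pregnancy_id", "series"], observed=True)["value"]
            .mean()
            .reset_index()
        )
        means["trimester"] = t
        rows.append(means)
    if not rows:
        return pd.DataFrame(columns=["pregnancy_id", "series", "value", "trimester"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Rank tests


def mann_whitney_u(
    x, y, comparison: str = "", m_comparisons: int = 4
) -> RankTestResult:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Uses the exact null distribution when n1*n2 <= 64 and there are no
    ties, otherwise the tie-corrected normal approximation with continuity
    correction.  The annotation applies the Bonferroni-corrected star
    thresholds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size * y.size <= 64 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return RankTestResult(
        comparison=comparison,
        u_statistic=float(res.statistic),
        p_value=p,
        n1=int(x.size),
        n2=int(y.size),
        annotation=annotate_p(p, m=m_comparisons),
    )


TRIMESTER_COMPARISONS = ((-1, 1), (1, 2), (2, 3), (3, 4))


def pairwise_trimester_tests(
    tri_means: pd.DataFrame, series: str
) -> pd.DataFrame:
    """Adjacent-trimester Mann-Whitney tests on per-pregnancy trimester means.

    One comparison per adjacent pair (-1 vs 1, 1 vs 2, 2 vs 3, 3 vs 4),
    Bonferroni-annotated for the four comparisons; a pair with fewer than
    two pregnancies in either trimester is omitted with a warning.
    """
    sub = tri_means[tri_means["series"] == series]
    rows = []
    for a, b in TRIMESTER_COMPARISONS:
        va = sub.loc[sub["trimester"] == a, "value"].to_numpy()
        vb = sub.loc[sub["trimester"] == b, "value"].to_numpy()
        if va.size < 2 or vb.size < 2:
            log.warning("trimester comparison %s vs %s omitted (insufficient pregnancies)", a, b)
            continue
        r = mann_whitney_u(va, vb, comparison=f"{a} vs {b}", m_comparisons=4)
        rows.append(
            {
                "series": series,
                "comparison": r.comparison,
                "U": r.u_statistic,
                "p": r.p_value,
                "n1": r.n1,
                "n2": r.n2,
                "annotation": r.annotation,
            }
        )
    return pd.DataFrame(rows)


def age_group(age_bin: str) -> str:
    """Map a survey age bin to the advanced-maternal-age dichotomy."""
    return "<35" if age_bin in AGE_BINS_UNDER_35 else ">=35"


def age_threshold_comparison(
    z_aligned: pd.DataFrame,
    survey: pd.DataFrame,
    series: str,
    bin_weeks: int = 1,
    day_range: tuple[int, int] = (-28, 280),
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-time-bin Mann-Whitney comparison of the < 35 and >= 35 groups.

    Days are grouped into ``bin_weeks``-week bins over ``day_range``; per
    bin the per-pregnancy bin means are compared between age groups, with
    Bonferroni correction across the bins actually tested within the
    series.  Bins with an empty group are skipped.
    """
    if bin_weeks not in (1, 4):
        raise ValueError("bin_weeks must be 1 or 4")
    groups = survey.set_index("pregnancy_id")["age_bin"].map(age_group)
    sub = z_aligned[
        (z_aligned["series"] == series)
        & (z_aligned["day"] >= day_range[0])
        & (z_aligned["day"] < day_range[1])
    ].copy()
    if sub.empty:
        return pd.DataFrame(columns=["series", "bin_start", "U", "p", "significant"])
    width = 7 * bin_weeks
    sub["bin_start"] = ((sub["day"] - day_range[0]) // width) * width + day_range[0]
    sub["group"] = sub["pregnancy_id"].map(groups)

    per_bin = (
        sub.groupby(["bin_start", "group", "pregnancy_id"], observed=True)["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for bin_start, grp in per_bin.groupby("bin_start"):
        lo = grp.loc[grp["group"] == "<35", "value"].to_numpy()
        hi = grp.loc[grp["group"] == ">=35", "value"].to_numpy()
        if lo.size == 0 or hi.size == 0:
            continue
        r = mann_whitney_u(lo, hi, comparison=f"bin {bin_start}")
        rows.append({"series": series, "bin_start": int(bin_start), "U": r.u_statistic,
                     "p": r.p_value, "n_lt35": r.n1, "n_ge35": r.n2})
    out = pd.DataFrame(rows)
    if out.empty:
        out["significant"] = []
        return out
    m = len(out)
    out["significant"] = out["p"] <= family_alpha / m
    return out
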