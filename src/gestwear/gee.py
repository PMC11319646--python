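"""Time-matched early-fetal-loss (EFL) GEE on post-loss temperature.

For each EFL pregnancy the seven days following its reported end of
pregnancy (DPS) are stored together with the same calendar-matched
seven-day windows (day indices relative to each pregnancy's own DKP)
from k randomly selected full-term pregnancies.  Nightly peak
temperature is linearly interpolated over interior gaps, smoothed with a
trailing 3-day mean, and z-scored against the pregnancy's -60..-30 day
baseline.  EFLs are grouped by pregnancy length (DKP to DPS) using
ordered thresholds; the assigned group value enters the model as a
numeric covariate.  The marginal model

    z_temp ~ day * category * length_threshold

(category: 0 = EFL, 1 = full term) is fitted with generalized estimating
equations, Gaussian family, grouping by pregnancy series, robust
standard errors, and an independence (default) or exchangeable working
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import GeeSpec

log = logging.getLogger(__name__)

#: Model terms in reporting order.
GEE_TERMS = (
    "Intercept",
    "Day",
    "Category",
    "Day:Category",
    "Length threshold",
    "Day:Length threshold",
    "Category:Length threshold",
    "Day:Category:Length threshold",
)

_PATSY_TO_TERM = {
    "Intercept": "Intercept",
    "day": "Day",
    "category": "Category",
    "day:category": "Day:Category",
    "length_threshold": "Length threshold",
    "day:length_threshold": "Day:Length threshold",
    "category:length_threshold": "Category:Length threshold",
    "day:category:length_threshold": "Day:Category:Length threshold",
}


def prepare_gee_series(
    aligned_series: pd.Series,
    mu: float,
    sigma: float,
    smoothing_days: int = 3,
) -> pd.Series:
    """Interpolate interior gaps, smooth (trailing mean), and z-score.

    ``aligned_series`` is day-indexed nightly peak temperature aligned by
    DKP.  Interpolation is linear over interior gaps only (no
    extrapolation beyond the observed ends).
    """
    from .profiles import rolling_mean, zscore_series

    s = aligned_series.dropna().sort_index()
    if s.empty:
        return s
    full = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1))
    interp = full.interpolate(method="linear", limit_area="inside")
    smoothed = rolling_mean(interp, smoothing_days)
    return zscore_series(smoothed, mu, sigma)


def assign_length_group(length_days: int, thresholds: tuple[int, ...] = (14, 28, 40, 60)) -> int:
    """Smallest threshold strictly greater than the pregnancy length."""
    for t in thresholds:
        if length_days < t:
            return t
    raise ValueError(
        f"pregnancy length {length_days} d exceeds the largest threshold {thresholds[-1]}"
    )


def sample_controls(
    efl_id: str,
    pool: pd.DataFrame,
    k: int,
    seed: int,
    eligible_ids: list[str] | None = None,
) -> list[str]:
    """k distinct full-term control pregnancy ids for one EFL, seeded.

    Sampling is without replacement within an EFL; the same control may
    serve multiple EFLs.  ``eligible_ids`` restricts the pool to controls
    with coverage over the matched window.
    """
    ids = list(eligible_ids) if eligible_ids is not None else list(pool["pregnancy_id"])
    if len(ids) < k:
        raise ValueError(
            f"EFL {efl_id}: only {len(ids)} coverage-eligible controls for k={k}"
        )
    if len(ids) == k:
        return sorted(ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _stable_hash(efl_id)]))
    return sorted(rng.choice(sorted(ids), size=k, replace=False).tolist())


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2**31)
    return h


@dataclass
class GeeDataset:
    data: pd.DataFrame  # long format rows
    n_efl: int
    n_control_series: int
    n_rows_dropped: int

    @property
    def n_series(self) -> int:
        return int(self.data["series_id"].nunique())


def build_gee_dataset(
    efl_records: pd.DataFrame,
    prepared: dict[str, pd.Series],
    pool_ids: list[str],
    spec: GeeSpec | None = None,
    seed: int = 0,
) -> GeeDataset:
    """Assemble the long-format time-matched dataset.

    ``efl_records`` needs pregnancy_id, dkp, dps; ``prepared`` maps
    pregnancy_id to its prepared (interpolated, smoothed, z-scored)
    day-indexed series.  For each EFL whose prepared series exists, its
    seven post-DPS days (offsets 0..6 at day indices length..length+6
    relative to DKP) are stored with the same day indices from k sampled
    controls.  Rows whose response is missing after interpolation are
    dropped and counted.
    """
    spec = spec or GeeSpec()
    rows = []
    n_dropped = 0
    n_controls = 0
    n_efl = 0
    offsets = np.arange(spec.post_days)
    for _, rec in efl_records.iterrows():
        eid = rec["pregnancy_id"]
        if eid not in prepared or prepared[eid].empty:
            log.warning("EFL %s has no prepared series; excluded", eid)
            continue
        length = int((pd.Timestamp(rec["dps"]) - pd.Timestamp(rec["dkp"])).days)
        threshold = assign_length_group(length, spec.length_thresholds)
        window = length + offsets

        efl_series = prepared[eid]
        if not (efl_series.index >= length).any():
            log.warning("EFL %s has no post-DPS days; excluded", eid)
            continue
        n_efl += 1

        def _coverage(pid: str) -> int:
            s = prepared.get(pid)
            if s is None or s.empty:
                return 0
            return int(s.reindex(window).notna().sum())

        eligible = [pid for pid in pool_ids if _coverage(pid) >= spec.min_window_days]
        controls = (
            sample_controls(eid, pd.DataFrame({"pregnancy_id": pool_ids}), spec.k_controls,
                            seed, eligible_ids=eligible)
            if spec.k_controls
            else []
        )
        n_controls += len(controls)

        for member, category in [(eid, 0)] + [(cid, 1) for cid in controls]:
            series_id = f"{eid}|{member}"
            vals = prepared[member].reindex(window)
            for off, day_idx, val in zip(offsets, window, vals):
                if pd.isna(val):
                    n_dropped += 1
                    continue
                rows.append(
                    {
                        "series_id": series_id,
                        "efl_anchor_id": eid,
                        "pregnancy_id": member,
                        "day": int(off),
                        "day_index": int(day_idx),
                        "z_temp": float(val),
                        "category": int(category),
                        "length_threshold": int(threshold),
                    }
                )
    data = pd.DataFrame(rows)
    return GeeDataset(
        data=data, n_efl=n_efl, n_control_series=n_controls, n_rows_dropped=n_dropped
    )


@dataclass
class GeeResult:
    terms: pd.DataFrame  # term, coefficient, se, z, p, ci_lo, ci_hi
    cov_struct: str
    n_groups: int
    n_obs: int

    def coefficient(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "coefficient"])


def fit_gee(dataset: GeeDataset | pd.DataFrame, spec: GeeSpec | None = None) -> GeeResult:
    """Fit z_temp ~ day * category * length_threshold with GEE.

    Grouping is by pregnancy series; robust (sandwich) standard errors;
    working correlation per ``spec.cov_struct``.  A rank-deficient design
    (e.g. a single length group, making the threshold collinear with the
    intercept) raises with advice to reduce the formula.
    """
    spec = spec or GeeSpec()
    df = dataset.data if isinstance(dataset, GeeDataset) else dataset
    if df.empty:
        raise ValueError("empty GEE dataset")
    if df["series_id"].nunique() < 2:
        raise ValueError("need at least two grouped series")

    design = df[["day", "category", "length_threshold"]].to_numpy(dtype=float)
    full = np.column_stack(
        [
            np.ones(len(df)),
            design[:, 0],
            design[:, 1],
            design[:, 0] * design[:, 1],
            design[:, 2],
            design[:, 0] * design[:, 2],
            design[:, 1] * design[:, 2],
            design[:, 0] * design[:, 1] * design[:, 2],
        ]
    )
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (e.g. a single length group makes the "
            "threshold collinear with the intercept); reduce the formula"
        )

    y = df["z_temp"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:  # constant response: closed-form degenerate fit
        rows = [
            {
                "term": term,
                "coefficient": float(y[0]) if term == "Intercept" else 0.0,
                "se": 0.0,
                "z": np.nan,
                "p": np.nan,
                "ci_lo": float(y[0]) if term == "Intercept" else 0.0,
                "ci_hi": float(y[0]) if term == "Intercept" else 0.0,
            }
            for term in GEE_TERMS
        ]
        return GeeResult(
            terms=pd.DataFrame(rows),
            cov_struct=spec.cov_struct,
            n_groups=int(df["series_id"].nunique()),
            n_obs=int(len(df)),
        )

    cov = sm.cov_struct.Exchangeable() if spec.cov_struct == "exchangeable" else sm.cov_struct.Independence()
    model = smf.gee(
        "z_temp ~ day * category * length_threshold",
        groups="series_id",
        data=df,
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    fit = model.fit()
    ci = fit.conf_int()
    rows = []
    for patsy_name, term in _PATSY_TO_TERM.items():
        rows.append(
            {
                "term": term,
                "coefficient": float(fit.params[patsy_name]),
                "se": float(fit.bse[patsy_name]),
                "z": float(fit.tvalues[patsy_name]),
                "p": float(fit.pvalues[patsy_name]),
                "ci_lo": float(ci.loc[patsy_name, 0]),
                "ci_hi": float(ci.loc[patsy_name, 1]),
            }
        )
    terms = pd.DataFrame(rows)
    return GeeResult(
        terms=terms,
        cov_struct=spec.cov_struct,
        n_groups=int(df["series_id"].nunique()),
        n_obs=int(len(df)),
    )


def gee_from_cohort(
    aligned: pd.DataFrame,
    survey: pd.DataFrame,
    baseline: pd.DataFrame,
    efl_ids: list[str],
    pool_ids: list[str],
    spec: GeeSpec | None = None,
    seed: int = 0,
) -> tuple[GeeDataset, pd.DataFrame]:
    """Prepare per-pregnancy z-series and build the GEE dataset.

    ``aligned`` is the DKP-aligned long daily table (must contain the
    ``temp_peak`` series); ``baseline`` is the output of
    :func:`gestwear.profiles.baseline_stats`.  EFLs with unusable
    baselines are excluded (logged), mirroring the loss of pre-onset data.
    Returns the dataset plus a per-pregnancy usability table.
    """
    spec = spec or GeeSpec()
    stats_tp = baseline[(baseline["series"] == "temp_peak")].set_index("pregnancy_id")
    temp = aligned[aligned["series"] == "temp_peak"]

    prepared: dict[str, pd.Series] = {}
    usability = []
    for pid, sub in temp.groupby("pregnancy_id"):
        if pid not in stats_tp.index:
            continue
        st = stats_tp.loc[pid]
        usable = bool(st["usable"])
        usability.append({"pregnancy_id": pid, "usable": usable, "n_baseline_days": st["n_days"]})
        if not usable:
            continue
        s = pd.Series(sub["value"].to_numpy(), index=sub["day"].to_numpy())
        s = s.groupby(level=0).mean()
        prepared[pid] = prepare_gee_series(s, st["mu"], st["sigma"], spec.smoothing_days)

    efl_records = survey[survey["pregnancy_id"].isin([e for e in efl_ids if e in prepared])]
    usable_pool = [p for p in pool_ids if p in prepared]
    dataset = build_gee_dataset(efl_records, prepared, usable_pool, spec=spec, seed=seed)
    return dataset, pd.DataFrame(usability)
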