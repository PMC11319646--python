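"""Seeded simulation studies used to validate the statistical machinery.

Each trial simulates a cohort with the generator's study conditions, runs
the full analysis path (alignment, baseline z-scoring, the statistic
under test), and reports whether the expected decision was reached:

* conception-rise detection — a +0.3 degC post-conception temperature
  rise should make the trimester -1 vs 1 comparison significant at the
  Bonferroni-corrected alpha of 0.0125;
* GEE sign recovery — the fitted Day, Day:Category, and three-way
  interaction coefficients should carry the signs implied by the
  generator (post-loss decline, flat controls, decline magnitude
  shrinking with loss day);
* type-I control — when the advanced-maternal-age split separates two
  identically generated groups, neither the per-bin comparisons nor the
  cumulative-distance endpoint test should reject more often than chance.
"""

from __future__ import annotations

import numpy as np

from .config import GeeSpec, SimulationConfig
from .cohort import align_cohort
from .distance import cohort_distances, compare_final_distance, daily_points, final_endpoints
from .gee import fit_gee, gee_from_cohort
from .profiles import (
    age_group,
    age_threshold_comparison,
    baseline_stats,
    pairwise_trimester_tests,
    trimester_means,
    zscore,
)
from .simulate import simulate_cohort


def _cohort_frames(cfg: SimulationConfig, seed: int):
    cohort = simulate_cohort(cfg, seed)
    aligned = align_cohort(cohort.daily, cohort.survey, anchor="dkp")
    return cohort, aligned


def conception_rise_trial(
    seed: int,
    n: int = 50,
    conception_rise: float = 0.3,
    noise_sd_temp: float = 0.1,
) -> float:
    """p-value of the trimester -1 vs 1 nightly-peak-temperature comparison
    for one simulated full-term cohort."""
    cfg = SimulationConfig(n_full_term=n, n_efl=0, conception_rise=conception_rise)
    cfg.noise_sd["temp_peak"] = noise_sd_temp
    _, aligned = _cohort_frames(cfg, seed)
    tm = trimester_means(aligned)
    tests = pairwise_trimester_tests(tm, "temp_peak")
    return float(tests.loc[tests["comparison"] == "-1 vs 1", "p"].iloc[0])


def conception_rise_detection(seeds: list[int], alpha: float = 0.05 / 4, **kwargs) -> float:
    """Fraction of seeds whose -1 vs 1 comparison is significant at alpha."""
    hits = [conception_rise_trial(s, **kwargs) <= alpha for s in seeds]
    return float(np.mean(hits))


def gee_sign_trial(
    seed: int,
    n_efl: int = 20,
    n_pool: int = 30,
    cov_struct: str = "independence",
    k: int = 5,
) -> dict[str, float]:
    """Fitted coefficients of the three sign-bearing terms for one cohort."""
    cfg = SimulationConfig(n_full_term=n_pool, n_efl=n_efl)
    cohort, aligned = _cohort_frames(cfg, seed)
    bstats = baseline_stats(aligned)
    survey = cohort.survey
    efl_ids = survey.loc[survey["outcome"].str.startswith("efl"), "pregnancy_id"].tolist()
    pool_ids = survey.loc[survey["outcome"] == "full_term", "pregnancy_id"].tolist()
    spec = GeeSpec(k_controls=k, cov_struct=cov_struct)
    dataset, _ = gee_from_cohort(aligned, survey, bstats, efl_ids, pool_ids, spec=spec, seed=seed)
    result = fit_gee(dataset, spec)
    return {
        "Day": result.coefficient("Day"),
        "Day:Category": result.coefficient("Day:Category"),
        "Day:Category:Length threshold": result.coefficient("Day:Category:Length threshold"),
    }


def gee_sign_recovery(seeds: list[int], cov_struct: str = "independence", **kwargs) -> float:
    """Fraction of seeds with sign-correct Day (<0), Day:Category (>0), and
    three-way (<0) coefficients."""
    hits = []
    for s in seeds:
        coefs = gee_sign_trial(s, cov_struct=cov_struct, **kwargs)
        hits.append(
            coefs["Day"] < 0
            and coefs["Day:Category"] > 0
            and coefs["Day:Category:Length threshold"] < 0
        )
    return float(np.mean(hits))


def null_age_trial(
    seed: int,
    n: int = 30,
    z_offset: float = 0.0,
    bin_weeks: int = 1,
) -> dict[str, object]:
    """One identically-generated age-split cohort: per-bin comparisons and
    the cumulative-distance endpoint test.

    ``z_offset`` adds a persistent z shift to the >= 35 group after
    normalisation (0 for type-I studies; positive for power checks).
    Returns per-test rejection flags and the endpoint Kruskal-Wallis
    statistic.
    """
    cfg = SimulationConfig(n_full_term=n, n_efl=0)
    cohort, aligned = _cohort_frames(cfg, seed)
    bstats = baseline_stats(aligned)
    z = zscore(aligned, bstats)
    survey = cohort.survey
    groups = survey.set_index("pregnancy_id")["age_bin"].map(age_group)
    if groups.nunique() < 2:
        return {"age_reject": False, "distance_reject": False, "h": 0.0, "p": 1.0,
                "n_bins_significant": 0, "skipped": True}

    if z_offset:
        shifted = z["pregnancy_id"].map(groups) == ">=35"
        z = z.copy()
        z.loc[shifted, "value"] += z_offset

    age_tests = age_threshold_comparison(z, survey, "temp_peak", bin_weeks=bin_weeks)
    age_reject = bool(age_tests["significant"].any()) if not age_tests.empty else False

    points = daily_points(z)
    dists = cohort_distances(points, groups)
    endpoints = final_endpoints(dists)
    if len(endpoints) < 2 or any(v.size < 2 for v in endpoints.values()):
        return {"age_reject": age_reject, "distance_reject": False, "h": 0.0, "p": 1.0,
                "n_bins_significant": int(age_tests["significant"].sum()), "skipped": True}
    kr = compare_final_distance(endpoints)
    return {
        "age_reject": age_reject,
        "distance_reject": kr.p_value <= 0.05,
        "h": kr.h_statistic,
        "p": kr.p_value,
        "n_bins_significant": int(age_tests["significant"].sum()) if not age_tests.empty else 0,
        "skipped": False,
    }


def null_rejection_rates(seeds: list[int], **kwargs) -> dict[str, float]:
    """Type-I rates of the age-bin and distance-endpoint tests across seeds."""
    results = [null_age_trial(s, **kwargs) for s in seeds]
    usable = [r for r in results if not r["skipped"]]
    if not usable:
        raise ValueError("no usable trials (all cohorts had a single age group)")
    return {
        "age": float(np.mean([r["age_reject"] for r in usable])),
        "distance": float(np.mean([r["distance_reject"] for r in usable])),
        "n_trials": len(usable),
    }


def distance_power(seeds: list[int], n_per_group: int = 40, z_offset: float = 0.5) -> float:
    """Fraction of seeds rejecting the distance endpoint test under a
    persistent z offset in one group."""
    hits = []
    for s in seeds:
        r = null_age_trial(s, n=2 * n_per_group, z_offset=z_offset)
        if not r["skipped"]:
            hits.append(r["distance_reject"])
    return float(np.mean(hits)) if hits else float("nan")
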