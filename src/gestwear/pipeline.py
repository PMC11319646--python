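"""End-to-end orchestration: simulate -> preprocess -> cohort -> analyses.

A single :class:`~gestwear.config.RunConfig` drives the run; each stage
writes its tabular outputs under the run directory and contributes row
counts to ``report.json``.  Reruns with the same configuration and seeds
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .cohort import align_cohort, build_cohort
from .distance import cohort_distances, compare_final_distance, daily_points, final_endpoints
from .gee import fit_gee, gee_from_cohort
from .preprocess import analysis_series, preprocess_pipeline
from .profiles import (
    age_group,
    age_threshold_comparison,
    baseline_stats,
    pairwise_trimester_tests,
    population_profile,
    trimester_means,
    zscore,
)
from .simulate import simulate_cohort

log = logging.getLogger(__name__)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "parquet":
        df.to_parquet(path.with_suffix(".parquet"), index=False)
    else:
        df.to_csv(path.with_suffix(".csv"), index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    fmt = config.output_format
    t0 = time.time()

    cohort = aligned = z = bstats = None
    try:
        if config.stages.get("simulate", True):
            cohort = simulate_cohort(
                config.simulation,
                config.seed,
                fixture=config.fixture,
                minute_pregnancies=config.minute_stream_pregnancies,
            )
            cohort.write(out, fmt=fmt)
            report["stages"]["simulate"] = {
                "status": "ok",
                "n_pregnancies": int(cohort.survey.shape[0]),
                "n_daily_rows": int(cohort.daily.shape[0]),
            }

        if config.stages.get("preprocess", True) and cohort is not None and cohort.samples is not None:
            aggregates = preprocess_pipeline(cohort.samples, cohort.sleep, config.preprocess)
            _write(aggregates, out / "daily_aggregates", fmt)
            series = analysis_series(aggregates)
            _write(series, out / "analysis_series_from_raw", fmt)
            report["stages"]["preprocess"] = {
                "status": "ok",
                "n_aggregate_rows": int(aggregates.shape[0]),
            }
        elif config.stages.get("preprocess", True):
            report["stages"]["preprocess"] = {"status": "skipped", "reason": "no raw samples"}

        if config.stages.get("cohort", True) and cohort is not None:
            result = build_cohort(cohort.survey, cohort.daily, config.alignment)
            _write(result.records, out / "cohort", fmt)
            report["stages"]["cohort"] = {
                "status": "ok",
                "n_included_full_term": int(result.full_term.shape[0]),
                "n_included_efl": int(result.efl.shape[0]),
                "exclusion_ledger": result.ledger,
            }
            included = set(result.included["pregnancy_id"])
            daily_inc = cohort.daily[cohort.daily["pregnancy_id"].isin(included)]
            aligned = align_cohort(daily_inc, cohort.survey, anchor="dkp")
            bstats = baseline_stats(aligned, config.alignment)
            z = zscore(aligned, bstats)
            _write(bstats, out / "baseline_stats", fmt)

        if config.stages.get("profiles", True) and aligned is not None:
            tm = trimester_means(aligned, config.alignment)
            tests = pd.concat(
                [pairwise_trimester_tests(tm, s) for s in sorted(aligned["series"].unique())],
                ignore_index=True,
            )
            _write(tests, out / "trimester_tests", fmt)
            prof = population_profile(
                z[z["series"] == "temp_peak"], seed=config.seed
            )
            _write(prof, out / "profile_temp_peak_z", fmt)
            age_tests = age_threshold_comparison(z, cohort.survey, "temp_peak", bin_weeks=1)
            _write(age_tests, out / "age_tests", fmt)
            report["stages"]["profiles"] = {
                "status": "ok",
                "n_trimester_tests": int(tests.shape[0]),
                "n_age_bins": int(age_tests.shape[0]),
            }

        if config.stages.get("distance", True) and z is not None:
            groups = cohort.survey.set_index("pregnancy_id")["age_bin"].map(age_group)
            points = daily_points(z)
            if points.empty or groups.loc[points["pregnancy_id"].unique()].nunique() < 2:
                report["stages"]["distance"] = {"status": "skipped", "reason": "one age group"}
            else:
                dists = cohort_distances(points, groups)
                _write(dists, out / "distance_series", fmt)
                kr = compare_final_distance(final_endpoints(dists))
                with open(out / "distance_test.json", "w") as fh:
                    json.dump(
                        {"H": kr.h_statistic, "p": kr.p_value, "group_sizes": kr.group_sizes},
                        fh,
                    )
                report["stages"]["distance"] = {
                    "status": "ok",
                    "H": kr.h_statistic,
                    "p": kr.p_value,
                }

        if config.stages.get("efl", True) and aligned is not None:
            result = build_cohort(cohort.survey, cohort.daily, config.alignment)
            efl_ids = result.efl["pregnancy_id"].tolist()
            pool_ids = result.full_term["pregnancy_id"].tolist()
            if not efl_ids or len(pool_ids) < config.gee.k_controls:
                report["stages"]["efl"] = {"status": "skipped", "reason": "insufficient cohort"}
            else:
                dataset, usability = gee_from_cohort(
                    aligned, cohort.survey, bstats, efl_ids, pool_ids,
                    spec=config.gee, seed=config.seed,
                )
                _write(dataset.data, out / "gee_dataset", fmt)
                gee_result = fit_gee(dataset, config.gee)
                gee_result.terms.to_json(out / "gee_result.json", orient="records", indent=1)
                report["stages"]["efl"] = {
                    "status": "ok",
                    "n_efl_series": dataset.n_efl,
                    "n_control_series": dataset.n_control_series,
                    "n_rows": int(dataset.data.shape[0]),
                    "n_groups": gee_result.n_groups,
                }
    except Exception as exc:  # stage failure: record and stop downstream work
        report["error"] = {"message": str(exc), "type": type(exc).__name__}
        log.exception("pipeline stage failed")

    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
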