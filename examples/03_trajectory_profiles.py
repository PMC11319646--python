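"""Baseline z-scoring, population profiles, and trimester rank tests.

Pregnancies are aligned by DKP (day 0), z-scored against their own
-60..-30 day pre-pregnancy baseline, summarised per day across the
cohort, and compared between adjacent trimesters with two-sided
Mann-Whitney tests under a Bonferroni correction for the 4 comparisons.
"""

from gestwear import (
    SimulationConfig,
    align_cohort,
    baseline_stats,
    pairwise_trimester_tests,
    population_profile,
    simulate_cohort,
    trimester_means,
    zscore,
)

cohort = simulate_cohort(SimulationConfig(n_full_term=40, n_efl=0), seed=3)
aligned = align_cohort(cohort.daily, cohort.survey, anchor="dkp")

tests = pairwise_trimester_tests(trimester_means(aligned), "temp_peak")
print("nightly peak temperature, adjacent-trimester Mann-Whitney tests:")
print(tests[["comparison", "U", "p", "annotation"]].to_string(index=False))
print("\n'-1 vs 1' compares the 13 pre-conception weeks with trimester 1;")
print("stars follow the Bonferroni-corrected ladder (* means p <= 0.0125).")

z = zscore(aligned, baseline_stats(aligned))
prof = population_profile(z[z["series"] == "hr_peak"], seed=3)
row = prof.set_index("day").loc[-14]
print(f"\nz-scored nightly peak HR at day -14 (the post-conception local peak):")
print(f"  median {row['median']:.2f} z, 95% CI [{row['ci_lo']:.2f}, {row['ci_hi']:.2f}], "
      f"n = {int(row['n'])} pregnancies")
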