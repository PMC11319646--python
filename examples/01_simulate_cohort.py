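"""Generate a small synthetic wearable-pregnancy cohort and inspect it.

Each pregnancy gets survey anchor dates (DKP = date know pregnant,
DPS = date pregnancy stop), an age bin, and daily nightly/24 h analysis
series with realistic cyclicity, conception response, missing days, and
-- for loss outcomes -- a post-loss temperature decline.
"""

from gestwear import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_full_term=8, n_efl=3)
cohort = simulate_cohort(cfg, seed=42)

print("survey rows:")
print(cohort.survey[["pregnancy_id", "age_bin", "dkp", "dps", "outcome"]].head(11).to_string())

one = cohort.survey.iloc[0]["pregnancy_id"]
sub = cohort.daily[(cohort.daily["pregnancy_id"] == one)
                   & (cohort.daily["series"] == "temp_peak")]
print(f"\n{one}: {len(sub)} nightly-peak-temperature days "
      f"spanning {sub['date'].min().date()} .. {sub['date'].max().date()}")
print("values are degC; the pre-conception segment cycles with a ~28-day period,")
print("then plateaus ~0.5 degC above the follicular baseline after conception.")
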