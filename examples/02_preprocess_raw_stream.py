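"""Clean a raw minute-resolution sample stream into daily aggregates.

The pipeline dedups timestamps, applies the two per-participant quantile
filters (5-95% then 2-98%), drops samples whose nearest activity reading
is below 0.5 MET (non-wear evidence), annotates sleep, and reduces each
day to mean / median / peak (90-95% rank band) / trough (5-10% band)
over both the 24 h and the 20:00-08:00 nightly window.
"""

from gestwear import SimulationConfig, preprocess_pipeline
from gestwear.simulate import PregnancySpec, simulate_minute_stream, simulate_pregnancy_series

cfg = SimulationConfig(nonwear_rate=0.05, missing_day_rate=0.0)
spec = PregnancySpec("P1", "G1", "30-34", "2020-06-01", "2021-02-15", "full_term")
daily = simulate_pregnancy_series(spec, cfg, seed=5).loc[0:3]  # four days
samples, sleep = simulate_minute_stream(daily, spec, cfg, seed=5)
print(f"raw samples: {len(samples)} rows across {samples['modality'].nunique()} modalities")

aggregates = preprocess_pipeline(samples, sleep)
nightly = aggregates[(aggregates["window"] == "nightly")
                     & (aggregates["modality"] == "temperature")]
print("\nnightly temperature aggregates (degC):")
print(nightly[["date", "mean", "median", "peak", "trough", "n_samples"]].to_string(index=False))
print("\npeak/trough are rank-band means; non-wear minutes (ambient temperature,")
print("MET < 0.5) were removed by the wear gate before aggregation.")
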