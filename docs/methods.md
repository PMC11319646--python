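# Methods

This note documents the models, conventions, and design choices behind
`gestwear`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Day grid and anchors

All analyses run on integer day grids. Day 0 is an anchor date from the
survey: DKP (date the pregnancy became known) for trajectory analyses, DPS
(date the pregnancy ended) for peridelivery and loss analyses. Conception is
modelled 28 days before DKP — consistent with a positive test arriving about
one cycle after the last menstruation, and with the first trimester being
defined as [−28, 63). Windows are half-open everywhere, which makes lengths
well defined: t−1 = [−91, −28) (63 d), t1 = [−28, 63) (91 d), t2 = [63, 154)
(91 d), t3 = [154, 252) (98 d), t4 = [252, 343) (91 d). The conventional
printed span of 97 days for trimester 3 differs by one day from any
consistent half-open grid with these boundaries; we fix the boundaries
{−28, 63, 154, 252} and document the discrepancy rather than adjust them.

Gestation length is (DPS − DKP) + 28 days; full term is ≥ 259 days
(37 weeks). The cycle-trough diagnostic (`detect_cycle_trough`) checks that
the last pre-DKP trough of nightly peak temperature sits near day −28; it is
reported only, never used to re-anchor.

## Preprocessing conventions

- **Quantile filters.** Two passes, 5–95 % then 2–98 %, computed by linear
  interpolation of order statistics; values strictly outside the band are
  dropped. Each modality stream is filtered separately within a participant:
  modalities live on incommensurable scales (MET ≈ 1, HR ≈ 65 bpm), so a
  pooled quantile pair would destroy both streams.
- **Wear gate.** A non-MET sample is dropped iff the nearest MET sample
  within ±60 s is strictly below 0.5 MET. The tolerance accommodates the
  differing cadences (1 min temperature/MET, 5 min HR/HRV, 30 s RR); the
  strict inequality keeps exactly-0.5 readings. MET samples are never gated.
- **Daily peak/trough.** "Average 90–95 % quantile" is read as the mean of
  sample values whose midpoint rank (i − ½)/n falls inside the band — robust
  for dense minute data — with an interpolated Q(0.925) fallback when the
  band is empty at small n. The alternative endpoint-mean reading is a config
  switch (`peak_definition`).
- **Nightly window.** The fixed clock interval [20:00, 08:00) local time,
  attributed to the date on which it starts. Sleep annotation (longest sleep
  row per night, ties broken by earliest start; asleep iff t ∈ [start, end))
  is carried on samples but the nightly aggregates use the fixed window.
- **Timestamps** are naive local times; timezone shifts and DST are out of
  scope.

## Baseline normalisation

Each pregnancy and series is z-scored against its own pre-pregnancy state:
z = (x − μ)/σ with μ, σ the mean and sample SD (ddof 1) of daily values over
days [−60, −30) relative to DKP. A baseline is *usable* only with ≥ 5
observed days and σ above float-noise level; pregnancies with unusable
baselines are excluded from z-scored analyses and counted. Population
profiles report the per-day cross-pregnancy median, interpolated 10–90 %
quantiles, and a 95 % CI of the median from a seeded percentile bootstrap
(B = 1000); days with n < 3 report a degenerate CI. The CI-of-the-median
choice follows the stated methods wording; bootstrap is used because no
analytic method was named.

Rolling means are trailing over *calendar* days with a minimum of one
observation, so gappy wearable series keep their day set and a post-gap
value averages only the days actually present in the window.

## Rank tests

Adjacent-trimester comparisons use the two-sided Mann–Whitney–Wilcoxon test
on per-pregnancy trimester means: exact null when n₁n₂ ≤ 64 with no ties,
otherwise the tie-corrected normal approximation with continuity correction.
Annotations follow the star ladder with Bonferroni correction for the four
comparisons: * p ≤ 0.0125, ** p ≤ 2.5e−3, *** p ≤ 2.5e−4, **** p ≤ 2.5e−5.
The advanced-maternal-age comparison (< 35 vs ≥ 35, mapped from the survey's
5-year bins) tests per-pregnancy bin means in weekly or 4-week bins, with
Bonferroni correction across the bins tested within a series.

## Cumulative multimodal distance

Per day, the four most complete z-scored series (temperature peak, trough,
HR, HRV) form a point in R⁴; a day is usable only with all four components.
Members of the reference group (< 35 by default) are scored against the
leave-one-out componentwise mean, others against the full reference mean.
Daily Euclidean distances are accumulated over days −28..252 (−4 to 40
weeks); unusable days contribute zero and carry the total forward — no
interpolation, so the cumulative series is nondecreasing by construction.
Endpoints are compared with a tie-corrected Kruskal–Wallis test. Because the
χ² reference is coarse for tiny groups (deviations up to ≈ 0.09 from the
exact permutation p at 5 per group), `compare_final_distance` switches to
the exact two-group permutation null when the pooled sample is ≤ 12; cohort-
scale comparisons always use the asymptotic path.

## Time-matched EFL GEE

Nightly peak temperature aligned by DKP is linearly interpolated over
interior gaps (no extrapolation), smoothed with a trailing 3-day mean, and
z-scored. Losses are grouped by pregnancy length DPS − DKP using ordered
thresholds (14, 28, 40, 60 days; the value assigned is the smallest
threshold strictly greater than the length, and the 14/28/40/63 variant is
available). For each loss, its 7 post-DPS days (day indices length..length+6
relative to DKP) enter together with the same day indices from k = 5
full-term pregnancies sampled without replacement per loss (reuse across
losses allowed — 22 usable losses × 5 = 110 control series necessarily reuse
a 97-pregnancy pool). Controls must cover ≥ 5 of the 7 matched days.

The marginal model is `z ~ day * category * length_threshold` with category
0 = loss and 1 = full term and the threshold numeric, grouped by pregnancy
series, Gaussian family, robust sandwich SEs, independence working
correlation by default (exchangeable available; the generator studies must
pass under both). The coding makes `Day` the post-loss decline itself,
`Day:Category` the control offset that flattens it, and the negative
three-way interaction the shrinking of the loss–control slope gap with later
losses. Rank-deficient designs (e.g. a single length group) raise rather
than silently drop terms; missing responses are dropped and counted, with
balance 7 × #series before drops.

## Synthetic cohort generator

The generator defines the study conditions under which the machinery is
validated; it emulates the qualitative structure of ring-derived pregnancy
physiology, not any specific participant:

- **Shapes.** Piecewise linear with plateaus — the simplest family carrying
  every qualitative feature: a triangle-wave nightly-peak-temperature cycle
  (default 28 d, 0.3 °C luteal amplitude, minimum at each cycle start so the
  last pre-conception trough lands at day −28); a post-conception rise to
  0.2 °C above the cycle peak holding ~8 weeks, then a monotone decline to
  just below the pre-pregnancy mean at delivery; an opposite-signed nightly
  trough trend; HR rising to a local peak at conception + 14 d, dipping,
  then climbing to a maximum ~3 weeks before delivery with postpartum
  return; HRV mirrored; mild RR and activity declines. Between-subject
  offsets and daily noise are Gaussian (temperature noise SD 0.1 °C —
  typical night-to-night variability; other series scaled accordingly).
- **Loss model.** From the loss day onward, nightly peak temperature
  declines linearly toward the pre-pregnancy baseline, clipped there, with
  per-day magnitude `intercept − per_day × loss_day` (defaults 0.25 and
  0.003 *per baseline-SD unit*). Slopes are expressed in baseline-SD units
  (converted using the baseline-window SD including measurement noise — the
  scale the downstream z-analysis observes) because that is the scale on
  which the loss analysis operates and it keeps the decline from completing
  within the 7-day analysis window, preserving the slope–loss-day relation
  the generator exists to induce; a °C reading is available via
  `efl_slope_units`. Other series relax exponentially to baseline
  (τ = 10 d). Ground-truth slopes are stored and must be recoverable by
  least squares on noiseless segments.
- **Raw streams.** Temperature/MET at 1-min cadence around the clock, HR/HRV
  at 5 min and RR at 30 s inside the night's sleep interval; values are the
  day mean plus a 24-h sinusoid (temperature peaking ~03:00, activity
  ~15:00) plus noise. Non-wear is injected as contiguous 30–240 min blocks
  with MET in [0, 0.5) and ambient temperature (24–28 °C), giving the wear
  gate something real to remove. Nights occasionally emit a shorter
  duplicate sleep row to exercise longest-sleep selection.
- **Fixture mode** reproduces the study-scale subject accounting: 52 partner
  reports and 392 out-of-window pregnancies (survey only); 224 delivered
  pregnancies of which 47 are generated sparse in one trimester, 76 carry an
  explicit "sparse around onset/offset" exclusion label (no numeric rule
  exists for these), 4 are preterm, and 97 survive; 34 losses of which 4 are
  failures to implant, 3 are generated sparse in trimester 1, 4 carry an
  explicit low-prior-completeness label, and 23 survive — one of the 23
  lacking all pre-onset data, so 22 enter z-scored analyses. Included
  pregnancies carry the demographics-table age bins and high-risk counts
  verbatim; one full-term participant and three loss participants contribute
  two pregnancies each, retained as independent units.

What the generator does *not* emulate: raw PPG/accelerometer signals,
timezone travel, device firmware changes, autocorrelated or non-Gaussian
noise, gestational complications other than loss, and any coupling between
modalities beyond their shared day grid. Passing tests therefore demonstrate
correctness of the machinery under clean, known-truth conditions — not
performance on real cohorts.

## Validation studies

Seeded studies in `gestwear.experiments` (also run by the acceptance
script) check that the machinery reaches the expected decisions under the
generator's conditions: a +0.3 °C conception rise at n = 50 and 0.1 °C noise
makes the −1 vs 1 trimester test significant at α = 0.0125 in ≥ 9/10 seeds;
the GEE recovers the Day / Day:Category / three-way signs in ≥ 8/10 seeds at
20 losses and k = 5 under both working correlations; and with identically
generated age groups, the per-bin comparisons and the distance endpoint test
reject in ≤ 10 % of 100 seeds. Problem sizes (50 pregnancies per recovery
trial, 30 per null trial, 100 null seeds) keep a full validation run to a
few minutes on one CPU while leaving the binomial assertions comfortable
margins.

## Known limitations

- DST/timezone handling is absent by design (naive local time).
- The "sparse around onset" exclusions have no numeric rule and are label-
  driven in fixture mode; a real deployment would need an explicit rule.
- The exact Kruskal–Wallis path enumerates two-group relabellings and is
  exponential in group size; it is gated to pooled n ≤ 12.
- GEE control sampling is whole-pool rather than within length group; the
  alternative was considered and left unimplemented since the matched-window
  design already time-aligns controls per loss.
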