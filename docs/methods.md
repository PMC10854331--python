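# Methods

## The instability index

The package operationalizes mood instability as the within-person sample
variance of a bounded ordinal PROM total score over a trailing window of
*k* consecutive non-missing bi-monthly assessments. The estimator is the
unbiased sample variance (denominator *k* − 1), matching the default of
mainstream statistical environments. Three window widths are supported —
*k* = 3, 6, 12, i.e. six months, one year, two years of scheduled visits —
with *k* = 6 the default.

**Window admissibility.** Windows are formed over the *k* most recent
non-missing observations, but a window whose time-index span exceeds
1.5 × (*k* − 1) scheduled intervals is skipped: a "one-year" variance
stretched over three calendar years by missed visits would not measure
one-year instability. The factor 1.5 tolerates isolated missed visits
(e.g. one gap inside a 6-window) without admitting grossly stretched windows.

**Window-width diagnostics.** For each candidate *k*, a LOESS smooth
(default span 0.75, the conventional default; locally linear, as implemented
by `statsmodels`' lowess) is fitted to each participant's raw-variance
sequence against window end index. The per-participant mean squared error
between raw and smoothed values and the SD of the raw values are averaged
across participants; the selected width minimizes the sum of the ascending
MSE rank and the descending SD rank (competition ranking, so exact ties are
detected; ties resolve to the smaller width and are logged). This makes the
verbal criterion "lowest MSE but highest SD" total. Participants with fewer
than five windows cannot be smoothed and are excluded with a warning. A
seeded 12:4:4 BD:PC:HC subsample utility reproduces the kind of small
diagnostic panel on which the one-year window was originally chosen.

**Scaling and thresholds.** Raw variances of all windows of all participants
for a scale form the pooling universe (deliberately independent of diagnostic
group). The continuous instability index is the z-score against the pooled
mean and sample SD. Categorical thresholds come from ranked percentiles
(*n* = 100): the *p*-th ranked percentile is the ⌈*p·n*/100⌉-th order
statistic, computed with exact integer rank arithmetic because the
floating-point *q* grid of `numpy.percentile(..., method="inverted_cdf")`
produces off-by-one ranks (e.g. the 7th percentile of 1..100 returns 8).
Other numpy percentile conventions remain selectable and are recorded in the
threshold metadata. A window is *low* if its raw variance is ≤ the
60th-percentile cutoff, *high* if ≥ the 95th-percentile cutoff, otherwise
*moderate*; on an all-distinct pooled sample this splits mass approximately
60 / 34 / 6 (the high stratum holds the ⌈0.95 n⌉-th order statistic and
everything above it, ~5–6%). Classification is monotone in raw variance, and
boundary values classify into the stratum named by the rule (cutoff value
itself: low at the 60th, high at the 95th). Percentile cutoffs live on the
raw-variance scale (so they can be drawn on raw-variance plots); the
continuous index used in models is the z-scaled value. Both are retained on
every window.

**Participant-level category.** How a participant's many window categories
collapse to a single threshold is genuinely open; two rules are implemented.
`max_attained` (default): the highest category any window reaches —
consistent with reading threshold membership as exceedance. `median_window`:
the classification of the participant's median raw variance — a robust
sensitivity alternative. The two disagree exactly for participants with
transient high-variance excursions, and with many windows per participant
`max_attained` concentrates mass in the upper strata (max of ~50 windows
exceeds the pooled 60th percentile for almost everyone with nontrivial
fluctuation); results should state the rule used. The continuous index is the
participant mean of z-values under both rules.

## Inferential models

All tests use α = 0.001, compensating for the large number of within-person
observations.

**Group contrasts.** The continuous index is modeled as
z ~ diagnostic group with a participant random intercept, fitted by REML
(`statsmodels` MixedLM). All three pairwise contrasts (BD−HC, BD−PC, PC−HC)
are derived from the fixed effects with Tukey–Kramer adjustment via the
studentized-range distribution, using between-cluster degrees of freedom
(participants minus groups); adjusted 95% intervals use the same critical
value. The standardized effect divides the contrast by the total outcome SD,
√(σ²_intercept + σ²_residual) — a d-type magnitude.

**Threshold membership.** For each category, a groups × {in-category,
not-in-category} table is tested with the Pearson chi-square (no continuity
correction, df = G − 1), plus all pairwise 2×2 tests reported both with and
without Yates correction. Expected counts are attached and a warning is
raised when any expected cell is below 5. A category empty in every group
yields a degenerate result (χ² = 0) rather than an error.

**Functioning model.** SF-12 MCS or PCS T-scores are regressed on diagnostic
group (reference HC), sex (reference male), race dichotomized white/non-white
(reference white), age at enrollment, and the participant-level instability
threshold entered as moderate-vs-low and high-vs-low indicators, with a
participant random intercept (REML). The participant-level category is
broadcast to all of that participant's observations. Missing outcomes are
handled by observation-level complete-case likelihood — the standard
mixed-model treatment — not imputation. Because every fixed effect is a
between-person quantity, p-values and intervals use a t reference with
between-cluster degrees of freedom (participants minus fixed effects), the
value a Satterthwaite approximation reduces to for this design; at a few
hundred participants this is what keeps 95% intervals at nominal coverage.
A threshold or group level with no participants makes the design
rank-deficient and raises an error naming the aliased term.

## The synthetic cohort generator

The generator emulates the statistical skeleton of a decade-long bi-monthly
bipolar cohort: groups BD / PC / HC (study-shaped preset: 385 / 71 / 147
participants, 61 scheduled timepoints = 10 years including baseline),
bounded ordinal scores, group-ordered within-person variance, missingness,
and SF-12 outcomes linked to latent instability.

Per participant and scale, the latent trajectory is
x_t = μ_ip + episode_shift(t) + e_t with AR(1) noise
e_t = φ·e_{t−1} + ε_t (φ = 0.3; stationary initialization). The innovation
SD is the scale's base value times a group multiplier (BD 2.0, PC 1.3,
HC 1.0 — BD gets four times the control innovation variance) times a
person-level lognormal frailty (log-SD 0.3), so instability varies both
between and within groups. BD participants additionally receive episodic
square-wave shifts (Poisson rate 0.5/year, geometric duration with mean two
assessments, amplitude 8 latent points; depressive episodes load on PHQ-9
and half on GAD-7, manic ones on ASRM). Observed scores are the latent value
rounded and clipped to the scale range; scores are deleted MCAR at rate 0.15
by default (an optional mood-dependent MNAR mode exists for sensitivity
work and is off by default). Baseline means and SDs (PHQ-9 6 ± 4, ASRM
7 ± 2, GAD-7 5 ± 3, innovation SDs 2.5 / 1.8 / 2.2) are set so typical
scores sit in the mild-symptom range with realistic spread.

Functioning T-scores follow the random-intercept linear model above with the
participant's standardized log innovation scale as the latent instability
term (default MCS coefficients: intercept 52, BD −12, PC −6, female −0.5,
non-white +0.5, age 0.08/yr, instability −3; random-intercept SD 6, residual
SD 8 — magnitudes chosen to resemble T-score-scale effects in long mood
cohorts). For coefficient-recovery studies,
`simulate_functioning_from_thresholds` instead generates outcomes from
known indicator coefficients applied to pipeline-derived categories, making
"fit recovers truth" well-posed. Every generated dataset carries a
`GroundTruth` record (frailties, latent instability, random intercepts,
episode windows, coefficients) and is byte-reproducible from its seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real cohorts: pharmacotherapy and treatment effects,
diagnostic conversion, informative dropout, item-level response processes,
scale-specific assessment calendars (real anxiety measures were added later
than mood measures), and any calibration of absolute effect sizes to the
motivating study (its data are DUA-restricted; only directions and the
method's internal consistency are checked).

## Numerical and testing choices

- Rolling variance is validated window-by-window against an independent
  two-pass oracle to 1e-10; variance is location-invariant and scales as c²
  (property-tested on in-range integer series).
- Lossless CSV round-trips require `float_precision="round_trip"` in
  `pandas.read_csv`; the default parser drops ULPs.
- Null calibration of the group model is checked at 1,250 participants per
  group (21 timepoints, one scale): with the person-level frailty
  heterogeneity the contrast SE at 100/group is ≈ 0.09 SD, so a ±0.1
  standardized-effect band only discriminates signal from Monte-Carlo noise
  at larger n; group sizes were set from the SE ∝ n^(−1/2) scaling.
- Coefficient recovery runs 20 replicates at 100/30/50 participants and 21
  timepoints; coverage is assessed over all coefficient × replicate pairs.
- The directional checks run on the full study-shaped preset (603
  participants, 61 timepoints, three scales), which completes in seconds.
- Degenerate inputs: all-equal pooled variances collapse both cutoffs to that
  value (warning, not error) and the low rule wins on the boundary; z-scaling
  a zero-spread pool is an error; empty instability series are excluded from
  participant tables with a log note.

## Known limitations

- Windows are defined in numbers of assessments; calendar-time-weighted
  variance and alternative instability metrics (RMSSD/MSSD, autocorrelation,
  entropy) are out of scope.
- The participant-level threshold rule is a convention, not an identified
  quantity; both shipped rules are reported rather than reconciled.
- Mixed-model inference uses the between-cluster t (no Kenward–Roger
  machinery); with observation-level (time-varying) covariates this df choice
  would be conservative.
- MCAR missingness understates the structure of real PROM non-response.
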