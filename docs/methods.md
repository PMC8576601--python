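# Methods

`actimood` implements an end-to-end analysis for screening depressive
symptoms from consumer-wearable data: a synthetic cohort generator, a
completeness-based quality-control stage, the extraction of ~122 named
digital biomarkers, a Spearman/FDR association screen with
covariate-adjusted regression, and gradient-boosted classification of
depression risk evaluated by repeated stratified cross-validation.
This note records the models, the defaults and the design decisions.

## Quality control

Device use time is inferred from the heart-rate channel: a minute is
*complete* iff at least one heart-rate sample falls inside it (a 10-s
device contributes 6 samples per worn minute, so requiring one sample
per minute is the per-time-point reading of completeness and is
device-rate agnostic). Days are local midnight-to-midnight; a day is
retained with ≥ 20 complete hours (boundary inclusive), and partial
first/last days are treated symmetrically — they qualify only if they
reach the threshold. Participants need ≥ 10 complete days and ≥ 3
weekday sleep nights. Participant-level mean heart rate and mean daily
steps are screened with Tukey fences (1.5 × IQR beyond the quartiles)
using linear-interpolation (type-7) quartiles; the convention is fixed
and pinned by tests.

## Digital biomarkers

**Activity.** Mean daily steps and sedentary minutes (all days,
weekdays, weekends), plus mean daily minutes of light, moderate
(3.0–6.0 METs, inclusive) and vigorous (> 6.0 METs) activity.
Sedentary time is waking time at ≤ 1.5 METs. Because a "below 3 METs"
light band would overlap the sedentary band, light activity is
operationalized as the disjoint (1.5, 3.0) MET band while awake.

**Sleep.** Contiguous 30-s stage epochs form device records; the
night's main episode is the longest record overlapping the 8 PM–noon
window (naps are discarded) and is assigned to the calendar date of its
offset (the wake-day), which keeps one night per day and aligns weekday
labels with the workday the night precedes. From each episode: time in
bed (epochs × 0.5 min), TST (TIB − wake), SE (TST/TIB), SOL (time to
the first non-wake epoch), and WASO counted only over the middle half
of the episode (epoch indices in `[floor(N/4), floor(3N/4))`).
Summaries are the mean and CV (SD/mean, ddof = 1) over nights, plus the
mean and SD of sleep offset and midpoint in hours since midnight of the
wake-day; pre-midnight midpoints enter the average as negative hours
and the mean is wrapped back to [0, 24), avoiding wrap-around
artifacts. Timing features need ≥ 3 nights (≥ 3 weekday nights for the
weekday variants).

**Circadian rhythm (nonparametric).** Computed on hourly-aggregated
steps and heart rate, for all days and for weekdays only (weekend days
are dropped *before* aggregation):

- IS = (N·Σ_h (x̄_h − x̄)²) / (p·Σ_i (x_i − x̄)²) with p = 24 — the
  variance of the mean 24-h profile over the total variance;
- IV = (N·Σ (x_i − x_{i−1})²) / ((N−1)·Σ (x_i − x̄)²) — fragmentation
  of the rhythm via successive hourly differences;
- ICV — the 24-h mean of per-clock-hour across-day CVs (SD/mean,
  ddof = 1), an instability counterpart to IS;
- M10/L5 — means of the 10 consecutive most / 5 consecutive least
  active hours of the average day, windows searched circularly;
  RA = (M10 − L5)/(M10 + L5);
- day-lag autocorrelation at 15/30/60-min aggregation:
  AC(k) = Σ_{i≤N−k}(x_i−x̄)(x_{i+k}−x̄) / Σ_i (x_i−x̄)² with k one day
  — the full-sample denominator exactly as in the standard printed
  estimator (a pair-count-normalized variant is not used).

Hours with no data propagate as missing: the formulas then use the
available points and complete successive pairs only. Constant series
leave these metrics undefined (NaN) rather than raising.

**Peak detection.** A streaming z-score detector on 15-min bins: a
point signals when it exceeds the trailing moving mean of the filtered
series by more than `threshold` trailing SDs over the previous `lag`
points; signalled points enter the trailing statistics with weight
`influence`; a maximal run of signalled points is one peak. Defaults
`lag = 12` bins (3 h), `threshold = 2.0`, `influence = 0.1`, all
configurable — the algorithm requires these parameters and no canonical
values exist for wearable step data, so they are fixed here and
documented. Only positive deviations signal (steps and heart-rate peaks
are upward events); when the trailing window is flat the SD is zero and
any positive deviation signals, which gives the exact "flat series plus
isolated spikes" behaviour. Reported features are the mean and SD of
the daily peak count.

**Extended cosinor.** The diurnal profile is fitted with a sigmoidally
transformed cosine,

    y(t) = floor + height · F(cos(2π(t − φ)/24)),
    F(c) = 1 / (1 + exp(−β(c − α))),

with width α ∈ (−1, 1) and steepness β > 0. Reported quantities are
the mesor (mean of the fitted curve over the day), amplitude (curve
maximum − mesor), acrophase φ wrapped to [0, 24), α, β, and the
pseudo-F statistic ((SS₀ − SSR)/(q − 1)) / (SSR/(n − q)) against the
constant model with q = 5 parameters. Because the model depends on
t mod 24 only, the least-squares problem is solved exactly on per-time
means weighted by their counts (the within-time scatter is an additive
constant of the objective); this is an algebraic identity, not an
approximation. Optimization is bounded trust-region least squares with
an analytic Jacobian, multi-start over acrophase {0, 6, 12, 18, argmax
hour} (the two cheapest starts are refined), and tolerance 1e-8
(tightened to 1e-14 in recovery tests). Noiseless model-generated
series are recovered to machine precision; constant series raise.

**Heart rate.** Overall mean HR weights each complete minute's mean
equally so 5-s and 10-s devices are comparable. RHR is the mean HR over
calendar-aligned, non-overlapping 15-min windows whose 15 minutes are
all complete and contain zero steps; delta HR = overall mean − RHR.
Day (2–4 PM) and night (12–2, 2–4, 4–6 AM) windows are summarized per
night and then averaged across nights — the reported CV is the mean
over nights of (window SD / window mean), ddof = 1 — rather than pooled
across nights; the night windows fall on the morning of the wake-day,
so per-calendar-day grouping is per-night grouping. RMSSD is computed
from raw samples (a gap longer than twice the typical sampling interval
breaks successiveness) and from hourly means (only adjacent hours
paired).

## Outcomes and subsamples

PHQ-9 totals (0–27) at two assessments give four depression rules:
A — ≥ 10 at either assessment; B — ≥ 8 at both; C — average ≥ 8; D —
top vs bottom 20% by average (ties broken by participant id; exactly
⌊0.2n⌋ per extreme). The 4×4 severity cross-tab (0–4 / 5–9 / 10–14 /
≥ 15 at T1 × T2) exposes helper counts (either/both ≥ 10, prevalence).
Contrasted subsamples pair the rule's depressed group with healthy
participants whose average score lies in (0, 4] — zero-average
participants are excluded as unreliable responders — randomly
downsampled to the depressed count (+2 for rule A, mirroring the
38-vs-40 design shape; exact balance for B/C). Rule D uses the score
ranges [7.5, 14] (depressed) and [0.5, 1.5] (healthy).

## Association screening and regression

Spearman rank correlation (midrank ties, two-sided asymptotic p — the
cohort scale makes the t approximation appropriate at n ≥ 10) between
every biomarker and the average PHQ-9 score, on pairwise-complete
observations; Benjamini–Hochberg adjustment across the roster.
Hierarchical regression fits block-nested OLS (listwise deletion):
biomarker alone, then + sociodemographics, then + lifestyle/health/
sleep/loneliness totals, with dummy coding against documented reference
levels. For proportion-like biomarkers an optional "per 10% change"
scaling reports β × 0.1 (a 0.1-unit step of a [0, 1]-scale feature);
the convention is configurable because no single standard exists.

## Screening models

Feature selection freezes the biomarker set on the full sample at raw
Spearman p thresholds (A: p < .01; B: p < .05; C: .01 ≤ p < .05), then
reuses it unchanged for every subsample model. The learner is extreme
gradient boosting with the DART booster; since no canonical
hyperparameters exist for this problem, defaults are fixed for
reproducibility at depth 3, 200 rounds, learning rate 0.1, drop rate
0.1, single-threaded. Evaluation is repeated (stratified, by default)
4-fold × 25-repeat cross-validation — 4 folds put 25% of the sample in
each holdout — with per-holdout confusion-matrix metrics (accuracy,
sensitivity, specificity, PPV, NPV, Cohen κ), per-fold AUC (pooled
predictions available behind a flag is deliberately *not* the default),
and the no-information rate alongside. Undefined rates (division by
zero) propagate as NaN and are skipped in fold averages. Gain-based
feature importances are normalized to sum 1 per fold and averaged.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis
assumes; it is the package's test bed, not a model of any particular
device's firmware.

- **Steps**: hourly templates (commute-like two-peak weekday profile,
  broad-midday weekend profile; participant-level activity multiplier
  lognormal with σ = 0.25) scaled by mean-preserving lognormal
  day-by-hour jitter (base log-SD 0.5), with negative-binomial-like
  minute counts (Poisson–gamma, variance > mean) and Poisson-count
  discrete activity bouts (4/day expected, 8–16 min, ~100 extra
  steps/min) that the peak detector can find. Steps are zero during
  sleep episodes.
- **Heart rate**: baseline N(66, 4) bpm + a cosine circadian component
  (trough ~4:30 AM, half-range 8 bpm) + activity coupling
  (0.08 bpm per step/min) + AR(1) noise (stationary SD 2 bpm,
  φ = 0.9 per sample) + extra independent nocturnal (0–6 AM) noise
  (SD 1.5 bpm) − 4 bpm during sleep; sampled every 10 s (5 s
  configurable).
- **Sleep**: one nightly episode (onset ~N(23.3, 0.5) h, duration
  ~N(7.4, 0.5) h clipped to 4–11 h); a semi-Markov wake/light/deep/REM
  block sequence with a geometric sleep-onset latency (mean 12 min) and
  ~6% body wakefulness. Naps are off by default.
- **Non-wear**: contiguous daily gaps removing heart-rate samples first
  (short charging/shower gaps of 18–150 min that never break the 20-h
  rule, and long forgotten-device gaps of 4.5–16 h that always do); the
  mixture weight is solved so the expected removed time matches the
  configured wear compliance. Gap intervals are recorded in a ledger
  for tests.
- **PHQ-9**: each participant's latent severity is standard normal,
  shifted by +2.4 for the depressed group; both totals share the
  expected score exp(0.85 + 0.6·severity) and differ by independent
  Gaussian noise whose variance is solved analytically from the
  configured test–retest correlation (default 0.73) via the
  lognormal-mixture variance, then rounded and clipped to 0–27. These
  constants were calibrated once against the descriptive statistics of
  the emulated working-adult cohort (mean total ≈ 4, ≈ 14%
  screen-positive under rule A, retest r ≈ 0.73). Negative target
  correlations are rejected: the shared-latent mechanism cannot
  produce them.
- **Covariates**: age, gender, ethnicity, marital status, education,
  income band, alcohol, smoking, self-rated health drawn to match the
  emulated cohort's margins; loneliness/sleep-quality/sleep-hygiene/
  sleepiness totals are weakly severity-coupled so they behave as the
  confounders they are.

**Planted effects.** `effect_sizes` maps a biomarker name to a shift
expressed per standard deviation of latent severity: each participant's
knob is moved by `effect × standardized severity`, so the
depressed–healthy contrast inherits ≈ 1.6 × effect biomarker-SDs
through the groups' severity gap while the severity-correlated Spearman
screen retains power. (A pure group-indicator shift at 15% prevalence
caps the attainable rank correlation near 0.17, which no FDR correction
over ~120 features can flag reliably at n = 200; severity-proportional
planting is the reading under which both the two-sample group contrast
and the screen-level recovery are achievable, and it is the more
realistic dose–response structure.) Supported knobs: `IS.st.wd`
(weekday template jitter ×e^(−0.6·s)), `NHR.0406.cv` (nocturnal HR
noise ×e^(0.5·s)), `peaks.st` (bout rate ×e^(0.35·s)), and
`sleep.midpoint` (rigid schedule shift of s hours).

**What the generator does not emulate**: device-specific firmware
noise, nap architecture and REM cycling fidelity, weekday/weekend
covariance structure beyond the two templates, seasonal or
menstrual-cycle rhythms, and measurement error in the PHQ-9 beyond
additive noise. Passing tests therefore demonstrate that the pipeline
recovers structure *of the kind the analysis assumes*, not that any
particular real-world effect size is reproduced.

## Problem sizes in tests and the acceptance script

Unit tests run on small cohorts (≈ 12 participants × 7 days). The
planted-effect recovery property uses 20 cohorts of n = 200 × 14 days;
the classification property uses one n = 420 cohort whose QC-retained
~250 participants yield a rule-A contrasted subsample of ~60–80 — the
scale at which the emulated design operates. At 14 days and 85%
compliance roughly half the cohort clears the 10-complete-day rule
(the emulated study tracked ~18 days, which is why its retention was
higher); the retained sample sizes are reported alongside every
statistic. The permutation null for Cohen κ is the mean over eight
label permutations — a single permutation of a ~60-participant sample
carries real chance structure with κ swings of ±0.2, so the mean is the
correct estimate of the null expectation.

## Known limitations

- The hierarchical-regression "per 10% change" scaling applies a fixed
  0.1-unit convention; features on other scales need explicit
  rescaling by the caller.
- Peak counts depend on the documented detector parameters; there is no
  device-independent ground truth for "a peak".
- The AC estimator's full-sample denominator makes AC ≤ (N−k)/N even
  for perfectly periodic data; this is a property of the printed
  estimator, preserved deliberately.
- QC treats sleep episodes as valid wherever staged epochs exist, even
  if heart-rate non-wear overlaps the episode; completeness governs
  activity/HR features only.
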