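# Methods

This note documents the models and procedures implemented in `wearcopd`,
the defaults they run under, the numerical choices behind them, and what
the synthetic data generator does and does not emulate.

## Study design being modelled

The pipeline targets a 90-day home-monitoring design for COPD patients
wearing a consumer smartwatch: to preserve battery, sensors record for
2 of every 10 minutes (a 20% duty cycle); the accelerometer samples at
20 Hz; heart rate is sampled continuously while recording; and patients
complete the 8-item London COPD cohort symptom questionnaire daily on a
paired phone. Sensor readings carry two validity flags — whether the
device was charging and whether the sensor's status register read
reliable — and only samples that were off-charger *and* reliable enter
any analysis.

## Diary scoring and episode detection

Daily score = 5 points per major symptom (dyspnea, sputum purulence,
sputum volume) + 1 point per minor symptom (nasal, wheeze, sore throat,
cough, fever). Episode rules: onset at the first day of 2 consecutive
days with score > 5; resolution at the last day of the first subsequent
run of 5 consecutive days with score exactly 0.

Choices where the rules are silent:

* **Missing days break runs.** Both the >5 run and the zero run require
  *present, calendar-consecutive* days. This is the conservative reading
  of "consecutive days": a patient who skips the diary neither
  accumulates onset evidence nor resolution evidence. A consequence is
  that detected episode counts fall and durations stretch as compliance
  drops — at the default ~72% compliance the 16-patient synthetic cohort
  yields roughly 10 detected episodes, versus ~24 at full compliance.
* **Thresholds are strict as printed**: a score of exactly 5 does not
  qualify for onset; resolution requires exactly 0.
* **Duration is inclusive** of both onset and resolution days.
* **No nesting**: scores above 5 inside an open episode extend it; a new
  onset requires prior resolution.
* **Open episodes** (unresolved at series end) have undefined duration
  but contribute their days to the exacerbation burden, defined as
  episode-days divided by the inclusive span from first to last present
  diary day.
* The detector is verified exhaustively against an independent
  brute-force scanning implementation over all 3^10 short score series
  and over randomized series with missing days.

Cohort mean scores are reported both as unweighted means of patient
means and as day-weighted pooled means; with unequal adherence the two
differ and neither is privileged.

## Accelerometry

The counts pipeline fixes an explicit, simple reading of
"area-under-the-curve motion summary after removing gravity":

* **Gravity estimate**: centred moving average per axis, window ≈ 2 s
  (odd sample count, reflected boundaries), applied within each
  contiguous recording burst; the residual is the motion component. The
  2 s window passes body-movement frequencies (≥ ~1 Hz) almost
  unattenuated while tracking slow orientation change.
* **Counts per minute**: trapezoidal integral of the Euclidean motion
  magnitude over each calendar-aligned 60 s epoch, linearly rescaled to
  the full minute when samples cover only part of it (under the duty
  cycle most minutes are either fully covered or empty). A scaling
  constant `count_scale` (default 1 count per (m/s²)·s) converts
  integrated magnitude to counts.
* **Minute validity**: ≥ 2 valid samples and ≥ 50% of the samples the
  device recorded in that minute surviving the charging/reliability
  filter. The 50% floor balances coverage against noisy, mostly-invalid
  minutes; because the recorded-sample denominator comes from the stream
  itself, the rule is automatically duty-cycle-aware.
* **Classification**: sedentary < 50.92 counts/min, MVPA > 305.36
  counts/min, light otherwise; inequalities strict, so boundary values
  are light. These cut-points come from a published validation of
  Android-device counts; they are meaningful relative to *a* counts
  pipeline, so absolute comparability with other implementations is not
  claimed — within this package the synthetic amplitudes and thresholds
  are mutually consistent.
* Daily summaries report % of valid minutes per class; they sum to 100
  for any day with ≥ 1 valid minute; days with none are no-data days.
* Counts are rotation-invariant (the magnitude is), which the tests
  check by rotating a synthetic stream.
* Gyroscope channels, step counting and non-wear detection beyond the
  validity flags are out of scope.

## Heart rate

Valid recordings are grouped by calendar day (mean, sample (n−1) SD,
count; a single-recording day gets SD 0). Per-patient summaries pool all
valid recordings exactly (reconstructed from per-day sufficient
statistics) and also carry the mean of daily means, since the pooling
convention matters when recording counts differ by day. No physiological
range filter is applied beyond bpm > 0. A "day of available data" is a
day with ≥ 1 valid recording — the weakest defensible reading, applied
uniformly across sensors.

## Availability summaries

Per-patient rows mirror a feasibility-study summary table: survey mean
(SD) score and days completed; heart-rate mean (SD) and days available;
mean daily %MVPA and %sedentary and activity days available (absent for
patients with no activity days). The cohort row uses unweighted means
over patients with zero-day patients included; day-weighted pooled
variants are emitted alongside because the conventions genuinely
diverge under unequal adherence and the published table's aggregation
cannot be recovered for every column (its activity-days column *is* the
unweighted mean — re-aggregating the embedded reference table gives
60.2 days and 13 of 16 patients with data — while its survey- and
heart-rate-day entries match neither convention exactly and are left
unasserted). Report rounding is half-even to 1 decimal; internal values
keep full precision.

## Synthetic cohort generator

Everything downstream is exercised against generated data with known
ground truth. Per patient, all randomness flows from
`SeedSequence((cohort_seed, patient_index, stream))`, one independent
stream each for latent state, accelerometer, heart rate and diary, so
cohorts are bit-reproducible and patients parallelizable. Timestamps
are UTC; a day is a half-open 24 h window from local midnight at a
fixed configurable UTC offset (default 0). Recording windows are
half-open `[on, off)`, aligned to duty-cycle boundaries from midnight.

**Latent exacerbation process.** A day-level two-state process: each
non-episode day starts an episode with probability
`episode_rate_per_day` (default 1.5/90, matching ~1.5 detected episodes
per completer over 90 days); the elevated-symptom phase is geometric
with mean `mean_episode_symptom_days` (default 9), minimum 2 days (the
onset rule cannot recover shorter episodes); a refractory gap of
`min_inter_episode_days` (default 28) follows each phase — clinically,
re-worsening within about four weeks is a relapse of the same event,
and the 5-zero-day resolution rule cannot separate closer events.
Symptom probabilities: majors 0.95 and minors 0.70 during episodes
(expected score ≈ 17.8, comfortably above the onset threshold), majors
0.02 and minors 0.05 otherwise. The baseline values are calibrated once
so that (a) false 2-day high runs are rare (per-day probability of a
spurious >5 score ≈ 1.4%), and (b) zero-score days are common enough
(~73%) that episodes resolve in weeks: resolved synthetic durations
average ~20 (SD ~12) days. With these defaults and full compliance the
detector recovers ≳ 95% of injected onsets within ±1 day.

**Wear model.** The watch charges for the first `charging_hours_per_day`
(default 8, overnight — samples are generated but flagged charging) and
is worn for the next `wear_hours_per_day` (default 16, matching the
device's practical battery life); any remaining hours produce no
samples. A fraction `unreliable_fraction` (default 5%) of samples is
flagged unreliable at random.

**Accelerometer.** Per recording window: constant gravity vector of
magnitude 9.81 m/s² with a fresh uniformly-random orientation, plus
zero-mean white Gaussian motion whose per-axis SD follows the hour's
intended class — 0 (sedentary), 1.5 (light), 6.0 (MVPA) m/s² — plus
white sensor noise (SD 0.05 m/s²). With `count_scale = 1` the expected
counts are ≈ 5, ≈ 142 and ≈ 570 counts/min respectively, straddling the
50.92/305.36 cut-points with wide margins (the cut-points themselves
are never altered). Waking hours draw their intended class i.i.d. with
probabilities (0.64, 0.266, 0.094), the cohort-level class mix the
analysis expects; charging/off hours are sedentary.

**Heart rate.** Samples every `hr_interval_seconds` (default 2 s — no
rate is prescribed by the design; seconds-scale sampling under the duty
cycle reproduces thousands of recordings per day) at
`baseline + class offset + noise`, floored at 30 bpm; per-patient
baselines are Normal(80.6, 4.5) bpm, offsets +15 (light) and +40 (MVPA),
noise SD 3 bpm. Because valid samples are concentrated in waking hours,
pooled daily means sit above the resting baseline — as they do for real
wrist devices worn by day.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: device dropout and multi-day transmission
gaps; postural/gait structure in acceleration (motion is white, so the
counts pipeline is exercised on amplitude, not waveform shape);
circadian or autocorrelated heart-rate structure beyond the activity
offset; symptom autocorrelation within a day-state; and diary-entry
errors. The per-axis point volume of the real device (which logged
roughly half a million accelerometer points per patient-day) is not
matched exactly; the generator produces 20 Hz × 3 axes over the duty
cycle (≈ 345,600 values per fully-worn day).

## Problem sizes

The default configuration is the study-scale condition set: 16 patients,
90 days, 20 Hz accelerometry, 2 s heart rate, ~72% diary compliance.
The analysis drivers write full-length diaries and heart-rate streams
but limit raw 20 Hz accelerometer output to the first 3 study days per
patient: the generator redraws the activity profile independently per
day, so additional raw days add volume (hundreds of MB of CSV at full
length), not information, for the per-minute pipeline. Monte-Carlo
checks use 50 patients (episode recovery), 20 seeds (heart-rate
recovery) and 3 patient-days (activity recovery), sizes at which the
binomial/Gaussian error of each estimate is far below the margins being
checked.

## Known limitations

* The counts pipeline is a self-consistent reading of an
  area-under-the-curve actigraphy method, not a replication of any
  proprietary algorithm; absolute counts are comparable only within
  this pipeline.
* Missing-day handling in episode detection (runs break) is one
  defensible convention; detected episode counts under partial
  compliance are sensitive to it.
* The cohort "All"-row aggregation for survey and heart-rate day counts
  in the published reference table cannot be reproduced from its
  per-patient rows under either convention emitted here; those entries
  are deliberately not asserted anywhere.
* `exacerbation_burden` divides by the first-to-last-present-day span;
  for patients with a single present day the burden is 0 or 1 by
  construction.
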