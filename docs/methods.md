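# Methods

## The staging model

`sleepstream` implements a deterministic, causal rule cascade over
trailing-window statistics of 1 Hz heart rate (HR, bpm), per-second RR
intervals (ms) and 3-axis acceleration (g).  Its physiological assumptions
are the classical ones: wakefulness shows elevated HR, short RR intervals and
movement; deep sleep (NREM3) shows the lowest and most stable HR; REM shows
wake-like cardiac activity with high HRV (SDNN) and muscle atonia; light
sleep (NREM1+2, merged into one class) is the unmarked default.  The
classifier is *on-the-fly*: the label at second `t` is a function of samples
`0..t` only, so appending data never revises an emitted label.  This is
enforced structurally — every window is trailing and shrinks during warm-up —
and verified by prefix-stability tests.

### Sleep onset

The recording is assumed to start with the subject awake.  Onset is the first
second `t` with

* drop: `smoothedHR[t] ≤ baseline − drop_delta`, where `baseline` is the
  median smoothed HR over the first `baseline_win` seconds, and
* stabilization: the sample std of smoothed HR over the trailing `stab_dur`
  seconds is `< stab_tol`,

requiring `t ≥ max(baseline_win, stab_dur − 1)`.  Treating stabilization as a
single full-window std check (rather than demanding the per-second std stay
low for a further `stab_dur` seconds) keeps the detection delay near
`stab_dur + smooth_win` after a step-like HR fall; on a 70→55 bpm step with
0.5 bpm noise the detector fires ≈ 135 s after the drop.  Onset search runs
once; after it succeeds the cascade may still emit WAKE (a mid-night
awakening) but the onset machinery is not re-armed.  A prefix shorter than
`baseline_win` yields "no onset yet", not an error.

### The cascade

Evaluated in strict order with short-circuiting — WAKE, DEEP, REM, LIGHT:

| rule | condition (motion-aware) |
|------|--------------------------|
| WAKE | `frac(HR > hr_th) ≥ x1` and `frac(RR < rr_th) ≥ x2` and `movement_count ≥ movement_min` |
| DEEP | `std(smoothed HR over win_size) < std_th`, admitted after dwell `x3` |
| REM  | `frac(SDNN > sdnn_th) ≥ x4` and `movement_count ≤ movement_max`, admitted after dwell `x5` |
| LIGHT| otherwise |

The accelerometer-free variant drops both movement clauses and replaces the
REM test with `frac(SDNN > sdnn_th1) ≥ f1 and frac(SDNN > sdnn_th2) ≥ f2`
(`sdnn_th1 ≤ sdnn_th2`); its DEEP rule is identical to the motion-aware one,
which is why the two variants mark the same deep-sleep seconds whenever the
other clauses are inert around deep segments.

Comparison conventions are fixed and documented: value-versus-threshold
comparisons are strict (`HR > hr_th`, `std < std_th`, `SDNN > sdnn_th`,
`‖Δacc‖ > acc_th`; exact ties never count), while fraction-versus-required-
fraction and count comparisons are inclusive (`frac ≥ x1`,
`count ≥ movement_min`, `count ≤ movement_max`).

### Dwell hysteresis

`x3`/`x5` (and `min_dwell_deep`/`min_dwell_rem` in the HR-only variant) are
minimum persistence guards: a transition *into* DEEP or REM is admitted only
once that stage's rule has held for the given number of consecutive seconds;
until then the previous label is held.  An interruption resets the run.  This
candidate-persistence formulation makes dwell behaviour predictable: raising
`x3` can only merge or drop DEEP episodes, never create new ones, and raising
`std_th` never decreases the number of seconds labelled DEEP (both are tested
properties).  WAKE and LIGHT transitions are immediate.

## Features

* `moving_average(x, smooth_win)` — trailing mean, window shrinking at
  warm-up.
* `trailing_std(x, win)` — trailing *sample* (n−1) standard deviation;
  `out[0] = 0` by convention.  Sample std is used everywhere, SDNN being
  conventionally a sample statistic.
* per-second SDNN — `trailing_std(RR, sdnn_win)`; the support window
  (default 60 s) is a package choice, config-exposed.
* movement — second `t` is "moving" when `‖acc[t] − acc[t−1]‖₂ > acc_th`.
  The first difference cancels the static gravity component, making the
  statistic independent of wrist orientation; `movement_count` counts moving
  seconds in the evaluation window.  The per-second RR value is taken as the
  latest completed beat-to-beat interval; how a device aggregates beats into
  a 1 Hz RR channel is outside the package's scope.

Two execution paths exist by design: a vectorized batch path
(`score_recording`, used also by calibration) whose window statistics are
computed with `sliding_window_view` reductions, and an incremental path
(`step`/`ScorerState`) that recomputes each statistic from ring buffers.
Both apply identical numpy reductions to identical sample windows, so their
labels agree exactly and the per-second features agree to well under 1e−9;
the suite asserts both.

## Parameters

| name | unit | default | role |
|------|------|---------|------|
| `win_size` | s | 90 | evaluation window for fractions / std / movement |
| `smooth_win` | s | 3 (motion) / 5 (HR-only) | HR moving-average span |
| `sdnn_win` | s | 60 | SDNN support window |
| `hr_th` | bpm | 64 / 68 | wake HR threshold |
| `rr_th` | ms | 900 | wake RR threshold |
| `acc_th` | g | 0.05 | per-second movement magnitude threshold |
| `std_th` | bpm | 2.0 | smoothed-HR std below which DEEP fires |
| `x1, x2` | – | 0.3–0.5, 0.4 | required HR/RR exceedance fractions |
| `x3, x5` | s | 30 | DEEP/REM dwell times |
| `x4` | – | 0.4 | required SDNN exceedance fraction (motion-aware REM) |
| `sdnn_th` | ms | 65 | SDNN threshold (motion-aware REM) |
| `sdnn_th1/2`, `f1/2` | ms, – | 50/70, 0.4/0.3 | two-threshold REM test (HR-only) |
| `movement_min/max` | counts | 3 / 1 | "enough movements" / "movements minimized" |
| onset `baseline_win, drop_delta, stab_tol, stab_dur` | s, bpm, bpm, s | 300, 8, 1.5, 120 | onset detector |

All defaults for the threshold-like parameters are **calibration artifacts**:
they were selected by `calibrate()` — an exhaustive, deterministic grid
search maximizing mean per-second balanced accuracy across labelled nights —
on synthetic nights drawn with the default physiology.  They encode nothing
about any real cohort and should be re-fitted on labelled recordings before
real use.  `calibrate()` breaks ties by grid order, so results are exactly
reproducible; `default_grid()` ships the modest starting grid used throughout
the package (smoothing span, window length, `std_th`, `hr_th`, and the
REM-side parameters — the knobs that move recognition most).

## The synthetic-night generator

`simulate_hypnogram` draws a semi-Markov stage sequence: a wake prologue
(default 900 s), then episodes whose stage is sampled with weights
`target_fraction / mean_episode_length`, tilted linearly across the sleep
period (deep weight `∝ 2(1−u)`, REM weight `∝ 2u` for sleep-time fraction
`u`), and whose length is exponential with a stage-specific mean (light 20,
deep 15, REM 18, wake 3 minutes; 60 s minimum).  A draw equal to the current
stage extends the ongoing episode, keeping occupancy unbiased.  Default
targets put light at ≈ 55% of sleep, deep at ≈ 19% concentrated early, REM at
≈ 24% concentrated late, the remainder intra-sleep wake — standard adult
sleep architecture.

`simulate_signals` renders stage-conditional physiology: HR as stage mean
plus AR(1) noise (coefficient 0.9, so windows carry structure rather than
white noise) with stage-specific sd, means/sds cross-faded over 30 s at stage
boundaries so onset and dwell logic face gradual transitions; RR as
`60000/HR` plus Gaussian beat-to-beat jitter whose scale sets the measured
SDNN regime (defaults 30/40/20/90 ms for wake/light/deep/REM); acceleration
as a gravity vector plus per-axis sensor noise (sd 0.005 g) and Poisson-timed
movement bursts (6 /min wake, 0.5 light, 0.1 deep, 0.02 REM; bursts never
cross into another stage, reflecting atonia).  The stage orderings — deep HR
lowest and most stable, REM SDNN highest, movement essentially wake-only —
are the features the cascade exploits.

The `PhysioConfig.exaggerated()` preset separates the regimes cleanly (HR
means ≥ 4 sd apart, REM SDNN ≥ 2× any non-REM, movement confined to wake)
and is used to show that the cascade recovers the generating hypnogram when
the feature space is separable.

**What the generator does not model** — and hence what passing tests do *not*
establish about real data: PPG sensor artefacts and missing beats,
respiratory sinus arrhythmia and other structured HRV spectra, inter-subject
baseline variability, arousal micro-structure, and any coupling between
movement and subsequent HR.  Synthetic results demonstrate the machinery's
correctness and the cascade's behaviour under its own assumptions, not
clinical accuracy.

## Evaluation conventions

* Confusion matrices are column-normalized per *true* stage, so columns sum
  to 100% and the diagonal is per-stage recall; columns for absent stages are
  flagged undefined (NaN), never silently zero.  Pooling across nights sums
  raw second counts before normalizing.
* Sleep–wake metrics take SLEEP = {LIGHT, DEEP, REM} as the positive class —
  the prevailing convention in wearable validation work.
* Advances are `time(reference) − time(algorithm)` (positive = algorithm
  earlier); TST/WASO differences are `algorithm − reference`.  Onset is the
  first non-WAKE second, wake-up one past the last.
* Stage latency matches each true episode of stage S to the first predicted
  S-second within `[start − match_back, episode end)`, `match_back = 300` s
  by default; unmatched episodes are excluded and counted.  The matching
  window is a package operationalization — latency tables in the literature
  rarely define one.

## Numerical and I/O choices

* Timestamps are integer epoch-seconds; recordings are half-open intervals.
  Gaps ≤ 5 s are imputed by last-observation-carried-forward with per-second
  `imputed` flags; larger gaps split the recording and classification
  restarts per segment.
* CSV round-trips are exact: values are written with shortest-round-trip
  formatting and parsed with `float_precision="round_trip"`.
* Physiological validity is enforced at construction: HR in (20, 250) bpm,
  RR in (200, 3000) ms, equal channel lengths, a closed four-label stage
  alphabet.
* All simulation randomness flows through `numpy.random.default_rng` seeded
  explicitly; there is no hidden global state.

## Problem sizes

The test suite exercises full 8 h nights where architecture matters
(simulator statistics over 100 nights; calibration + recovery over 10 nights)
and compressed 10–25 min nights with proportionally scaled windows for the
many per-second contract checks (prefix stability across 50 nights × 20
truncation points; streaming/batch equality across 100 fixtures), keeping the
default run around half a minute.  `scripts/acceptance.py` uses 2 calibration
+ 4 evaluation nights of 8 h per variant and 10 recovery nights.

## Known limitations

* The rule cascade has no learned components; its accuracy on real data is
  bounded by how well the threshold physiology holds for a given subject
  (beta-blockers, athletes and arrhythmia will shift every HR-based rule).
* Onset detection requires a clean wake baseline at recording start; a user
  who straps the watch on mid-sleep violates the model.
* The per-second RR convention discards intra-second beat detail, so
  short-window HRV measures (e.g. RMSSD) are not meaningful here and are not
  provided.
* Latency and advance metrics depend on the matching conventions above;
  compare numbers across tools only after aligning conventions.
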