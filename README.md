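# sleepstream

On-the-fly sleep staging from smartwatch-grade signals: a causal, per-second
classifier that labels every second of a night as **WAKE**, **LIGHT** (NREM1+2),
**DEEP** (NREM3) or **REM** using only 1 Hz heart rate (HR), per-second RR
intervals and 3-axis wrist acceleration — the channels a consumer wearable
exposes.  Because the label at second *t* depends only on samples up to *t*,
the classifier can run live while the subject sleeps, which matters for
applications that must react to the current stage (e.g. preventing a resting
driver from sinking into deep sleep before a takeover request).

The package is aimed at researchers evaluating wearable sleep-staging
pipelines against polysomnography (PSG) scorings, and at anyone who needs a
transparent, deterministic baseline stager with a full evaluation suite and a
synthetic data generator for testing.

## The algorithm

The stager assumes the user is awake when recording starts and first searches
for the physiological HR fall that marks **sleep onset**: the moving-average
HR must drop `drop_delta` bpm below the wake baseline (median smoothed HR over
the first `baseline_win` s) and then stabilize (std of smoothed HR over the
trailing `stab_dur` s below `stab_tol`).  From onset onward, every second is
classified by a short-circuiting rule cascade over trailing-window statistics
(window `winSize`, thresholds `hrTh`, `rrTh`, `accTh`, `stdTh`, fractions and
dwell times `x1 … x5`):

```
IF   frac(HR > hrTh) ≥ x1  AND  frac(RR < rrTh) ≥ x2  AND  enough movement
                                              → WAKE
ELIF std(smoothed HR) < stdTh   [after dwell x3]
                                              → DEEP
ELIF frac(SDNN > sdnnTh) ≥ x4  AND  movement ≈ 0   [after dwell x5]
                                              → REM
ELSE                                          → LIGHT
```

SDNN (the sample standard deviation of RR/NN intervals over a trailing
support window) is the HRV magnitude that separates REM — wake-like cardiac
activity with total muscle atonia — from NREM sleep; deep sleep is the
low-and-stable HR regime.  A second, **accelerometer-free variant** drops the
movement clauses and replaces the REM rule with a two-threshold SDNN test
(`frac(SDNN > sdnnTh1) ≥ f1 AND frac(SDNN > sdnnTh2) ≥ f2`), for settings
where wrist acceleration is unusable (e.g. at the wheel).

Dwell times `x3`/`x5` are hysteresis guards: a DEEP/REM transition is only
admitted once its rule has held for that many consecutive seconds; until then
the previous label is held.

The evaluation suite compares hypnograms second by second: a 4×4
column-normalized confusion matrix, binary sleep–wake sensitivity / precision
/ accuracy (SLEEP = LIGHT ∪ DEEP ∪ REM as positive class), signed sleep–wake
pattern deltas (sleep onset, final awakening, TST, WASO) and per-stage
recognition latency.  A semi-Markov night simulator with stage-conditional
physiology makes every component testable without access to clinical data.

## Worked example

Simulate a night, score it with the motion-aware cascade, and evaluate the
result against the generating hypnogram:

```bash
python -m sleepstream simulate --nights 1 --seed 7 --outdir sim
python -m sleepstream score --variant motion-aware \
    --input sim/night000_recording.csv --output pred.csv
python -m sleepstream evaluate --truth sim/night000_hypnogram.csv --pred pred.csv
```

which prints:

```
Confusion matrix (% of true-stage seconds; rows = predicted)
                 WAKE    LIGHT     DEEP      REM
  WAKE          93.89     9.67     4.11     6.64
  LIGHT          4.83    73.20     9.05     6.14
  DEEP           0.00     7.33    83.54     0.00
  REM            1.28     9.80     3.29    87.23
Sleep-wake: sensitivity=91.74% precision=98.18% accuracy=92.21%
Advances (s, + = algorithm earlier): onset=-1071 wake-up=+0; TST diff=-1477 WASO diff=+406
Latency WAKE   +29.8 s  (12/12 episodes matched)
Latency LIGHT  +66.7 s  (9/9 episodes matched)
Latency DEEP   -120.0 s  (2/3 episodes matched)
Latency REM    +54.6 s  (7/7 episodes matched)
```

Each confusion column sums to 100% over the predicted stages, so the diagonal
is per-stage recall: here 83.5% of true deep-sleep seconds were recognized as
DEEP.  The negative onset advance means the algorithm declared sleep about 18
minutes after the reference onset (it must first observe the HR fall and
stabilization), which also shows up as under-counted total sleep time (TST
diff < 0); latencies are `time(reference) − time(algorithm)` per stage
episode, positive when the algorithm anticipated the stage.

The same pipeline is available as a library:

```python
from sleepstream import (NightConfig, PhysioConfig, StagingConfig,
                         simulate_night, score_recording, evaluate_night)

rec, truth = simulate_night(NightConfig(), PhysioConfig(), seed=7)
pred = score_recording(rec, StagingConfig(), "motion_aware")
report = evaluate_night(truth, pred)
print(report.summary)
```

The shipped `StagingConfig` / `HrOnlyConfig` defaults are calibration
artifacts fitted on synthetic nights; re-calibrate on labelled recordings
(`sleepstream calibrate`, or `sleepstream.calibrate()` over a config grid)
before using the stager on real data.

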