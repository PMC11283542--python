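# qdg — Quantitative DigitoGraphy analysis

Objective measurement of the motor signs of Parkinson's disease from
thirty seconds of repetitive alternating finger tapping (RAFT) on a
two-lever keypress device.  The package takes raw two-channel lever
displacement traces (mm at a nominal 200.96 Hz) and produces:

* **strike cycles** — press / dwell / release events per finger, with
  per-strike kinematics, via a hysteresis state machine;
* **kinematic metrics** — press amplitude and its CV (sequence
  effect), inter-strike interval (ISI) and its CV (arrhythmicity),
  press speed, release slope, dwell time, rest tremor %, taps per
  minute; averaged per finger, then per hand;
* **per-strike tremor labels** — a retrainable gradient-boosted
  classifier plus a deterministic rate/amplitude rule fallback;
* **normative z-scores** — against a healthy-control reference with
  linear age adjustment to age 60 and 25th/75th-percentile
  abnormality flags;
* **composite scores** — the 0–100 **Mobility Score**,

      Mobility = 100 − 14 · (1/6) Σᵢ zᵢ,

  over six oriented, zero-capped z-scores (ISI, ISI CV, press speed,
  press amplitude, press amplitude CV, release slope), with a power-law
  compression `z' = 3.2 · z^0.495` (clipped at 20) of extreme
  press-amplitude z-scores; and the 0–100 **Tremor Severity Score**
  combining tremor duration and normalised tremor amplitude;
* **remote-monitoring analytics** — testing-day compliance (the
  16-of-30-day rule), prescribed-vs-taken medication matching, daily
  off/on views and OLS score trends, exported as a dashboard-style
  JSON report.

A seeded trace simulator with strike-level ground truth stands in for
the hardware device and drives the test oracle, the classifier
training, and the normative-reference examples.  It is written for
researchers and engineers building or evaluating keypress-based
digital motor biomarkers; the library API is the primary interface,
with a thin `qdg` command-line wrapper for file-based workflows.

## Worked example

`examples/score_a_trial.py` fits a normative reference on a simulated
healthy cohort and scores three simulated phenotypes:

```
normative press amplitude: 8.70 +/- 0.11 mm (abnormal below 8.65 mm)
        healthy: mobility  98.2  tremor severity   0.0  press amp 8.71 mm  rest tremor 0.0%
   bradykinetic: mobility   0.0  tremor severity   0.0  press amp 2.90 mm  rest tremor 0.0%
tremor_dominant: mobility   0.0  tremor severity  18.3  press amp 7.79 mm  rest tremor 21.6%
```

Healthy tapping (full ~8.7 mm presses at 2.5 cycles/s per finger)
scores near the ideal 100.  The bradykinetic phenotype — shallow,
decaying presses at a slow rate — collapses to the score floor against
the tight healthy reference.  The tremor-dominant phenotype keeps
near-normal voluntary presses but spends ~22% of the trial in 5 Hz
low-amplitude tremor strikes, giving a nonzero Tremor Severity Score.

The other examples cover segmentation against simulator ground truth
(`simulate_and_segment.py`), classifier training
(`train_tremor_classifier.py`), and a month of monitoring analytics
(`remote_monitoring.py`).  Each prints what it computes and a line on
what the numbers mean.

A file-based workflow via the CLI:

```sh
qdg simulate --phenotype healthy --seed 3 --out trial.csv
qdg analyze trial.csv                  # QC + metrics as JSON
qdg fit-reference cohort.csv --out reference.json
qdg score trial.csv --reference reference.json
```

Traces are CSV (`t_s, lever_a_mm, lever_b_mm`) with a JSON sidecar for
subject metadata and therapy context; see `docs/methods.md` for the
full model description, parameter defaults and limitations.

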