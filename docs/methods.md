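# Methods

`qdg` analyses two-lever repetitive alternating finger tapping (RAFT):
a 30-second task in which the index and middle finger press and release
adjacent tensioned levers "as fast and as regularly as possible".  The
lever displacement (mm, 0 = lever up) is sampled on a uniform grid at a
nominal 200.96 Hz.  This note records the models, the tunable
parameters, the numerical choices, and what the synthetic data do and
do not establish.

## Strike segmentation

Each channel is scanned by a four-state machine:

* **IDLE → PRESS** on an upward crossing of the onset threshold
  (default 5% of the 10 mm device range, i.e. 0.5 mm).  The onset is
  then back-projected along the monotone rise to the last local
  minimum, so press duration and press speed describe the whole
  excursion, not only its above-threshold part.
* **PRESS → DWELL** at the first sample that stops raising the running
  peak while staying within the dwell band (default 2% of range,
  0.2 mm) of it.  Noise ripple on the plateau may raise the peak later;
  the dwell start is kept at the first flattening.
* **DWELL → RELEASE** when the signal leaves the band downward.
* **RELEASE → IDLE** when the signal falls below *half* the onset
  threshold.  The asymmetric exit is a Schmitt trigger: with a single
  shared threshold, sensor noise straddling it during a release would
  split one strike into several.  With bounded noise below half the
  onset threshold, strike counts are provably unaffected, which is the
  robustness contract the test suite enforces.

Strikes whose peak is below `min_strike_amplitude` (default 0.5 mm) are
diverted to a debug list — they are incidental lever contact, not taps.
A strike truncated by the end of the recording is dropped because its
release kinematics are undefined.  Alternation between fingers is never
enforced (patients violate it); an alternation-violation count is
reported as a diagnostic.

Timing quantisation: the detected press duration carries a constant
overhead of roughly two sample periods (one from onset back-projection,
one from dwell entry).  At 200.96 Hz this is ~10 ms on a ~110 ms press.
Consequences: (i) extracted press speed is a few percent below the
generator's nominal value; (ii) a linear trend injected into the
generator's press-speed knob appears at about 0.8× its nominal size
after extraction.  Both are properties of any threshold-based detector
at finite sampling and are covered by detection-style tests rather than
exact-recovery tests.

## Trial metrics

Per finger, averaged over the trial's strikes (voluntary strikes only,
by default): press amplitude (mm), press amplitude CV, inter-strike
interval (ISI, onset-to-onset per finger, s), ISI CV, release slope
(release amplitude / release duration, mm/s), press speed (press
amplitude / press duration, mm/s), dwell time (s).  Hand values are the
unweighted mean of the two fingers; a finger with no usable strikes is
flagged and the hand value falls back to the other finger.  CVs use the
sample (n−1) standard deviation.  Taps per minute counts both fingers'
voluntary strikes over the trial duration; arrhythmicity is surfaced as
ISI CV × 100.

Rest tremor % is the union of tremor-labelled strike intervals
(onset → release end) divided by the trial duration.  The union, rather
than a plain sum, keeps simultaneous bilateral tremor from exceeding
100%.  ISIs are computed between consecutive *retained* strikes of a
finger; when tremor strikes are excluded, the interval spans the gap.

## Tremor classification

Rest tremor appears as runs of fast (3–8 Hz), low-amplitude strikes.
Two per-strike classifiers sit behind one interface:

* a deterministic rule — tremor iff instantaneous rate ≥ 3 Hz **and**
  amplitude < 30% of device range; first strikes (no preceding
  interval) default to voluntary;
* a gradient-boosted tree classifier (XGBoost; 100 trees, depth 4,
  learning rate 0.2, single-threaded and seeded for determinism)
  trained on simulator-labelled strike features: amplitude, previous
  ISI, instantaneous rate, press speed, release slope, dwell time,
  normalised amplitude.  Models serialise to JSON with a provenance
  block (seed, training counts, held-out balanced accuracy).

On simulator data both are near-ceiling because simulated tremor is
well separated in rate-amplitude space; the held-out balanced accuracy
bound (≥ 0.9) and the rule-dominance check are therefore regression
guards, not evidence about clinical traces.  No rest-vs-action tremor
distinction is attempted.

## Normative reference and z-scores

For each metric the healthy-control (HC) distribution supplies a mean,
SD and abnormality threshold.  Age effects are fitted only for press
amplitude CV, release slope and press speed — a mixed model with fixed
age effect and random intercept per subject (two hands per subject),
falling back to OLS on subject means if the mixed fit is degenerate.
Values are adjusted to the reference age of 60 years:

    adjusted = value + slope × (age − 60)

and the normative mean/SD and percentile thresholds are computed on the
adjusted HC values, so z-scoring is internally consistent.  Thresholds
are the 25th HC percentile for lower-is-worse metrics (press amplitude,
press speed, release slope, taps per minute, Mobility Score) and the
75th for higher-is-worse (ISI, ISI CV, press amplitude CV, dwell time,
rest tremor %); the boundary value itself counts as normal.  The
directions for ISI, dwell time and rest tremor % are package choices
recorded in `qdg.normative.DIRECTIONS`.

The reference ships as a versioned, editable JSON artifact.  Any
shipped or example reference is fitted on the **simulator** HC cohort,
not on a clinical cohort; its means are realistic (full press
8.67 ± 0.12 mm) but its timing-metric SDs are narrower than a real
population's, so patient-like trials can hit extreme z-scores.

## Composite scores

**Mobility Score.**  Six metrics enter: ISI, ISI CV, press speed, press
amplitude, press amplitude CV, release slope.  Raw z-scores are
oriented so larger = worse, capped below at 0 (above-average
performance must not inflate the score).  Because HC press amplitudes
cluster tightly, oriented press-amplitude z values above 10
(amplitudes below ≈ 7.5 mm) are compressed with a power law
`z' = 3.2 · z^0.495`, clipped at 20; the transform is continuous at the
activation point to within 0.004 and, with the clip, never exceeds 20
(the un-clipped law would reach ≈ 26.6 at the z ≈ 72 that a 0 mm press
produces).  Then

    Mobility = 100 − 14 × mean(oriented z),  clamped to [0, 100].

**Tremor Severity Score.**

    Severity = (pct + 100 · f(pct) · meanAmp / ampMax) / 2

with `pct` the rest-tremor percentage, `meanAmp` the mean tremor-strike
amplitude, `ampMax` the device maximum (default 10 mm, configurable —
it is a device property).  For `pct < 10`, `f(pct) = 4^(0.05·pct) − 1`
suppresses the amplitude term (f → 0 as pct → 0); above the knee
f = 1.  This multiplicative reading is the only one that both
suppresses amplitude for trace amounts of tremor and is exactly
continuous at the 10% knee (f(10) = 4^0.5 − 1 = 1).  The score is
clamped to [0, 100].

## Trace simulator

The simulator is the package's oracle and training source.  A strike is
a cosine-ramp press, flat dwell, cosine-ramp release; fingers tap half
a cycle out of phase at the configured per-finger rate, with
per-strike depth drawn from a normal distribution, optional per-strike
exponential depth decay (the sequence effect), ISI jitter, and additive
Gaussian sensor noise clipped to the physical range.  Tremor is
modelled as contiguous burst windows (~3 s each) covering a configured
fraction of the timeline, inside which voluntary taps are replaced by
oscillatory strikes at the tremor rate (45% press / 45% release of each
tremor period, so strike spans tile the burst) on both levers.  Every
emitted strike carries ground truth; everything is deterministic given
the profile seed.

Phenotype presets: *healthy* (2.5 cycles/s per finger, full press
8.67 ± 0.12 mm, 3% ISI jitter), *bradykinetic* (1.2 cycles/s, 4 mm
presses decaying 2%/strike, slow phases), *tremor_dominant* (near-
normal tapping, 25% of the timeline in 5 Hz 1.5 mm bursts), *mixed*.
Cohort generation adds mild between-subject variation (depth shifts at
the trial-level SD, phase durations ±8%, dwell ±10%, jitter ±30%
relative) and can inject linear age effects, in metric units per year,
through the controlling generator knobs.

What the simulator does **not** emulate: biomechanical finger/lever
dynamics, incomplete or merged presses, drifting baselines from
fingers resting on keys, action tremor superimposed on voluntary
strikes, or device calibration error.  Passing tests therefore
establish the correctness of the algorithms under the stated signal
model, not clinical performance.

## Monitoring analytics

Compliance counts distinct calendar test days over a calendar window
(both ends inclusive; enrollment gaps are not excluded); the 16-of-30
criterion is `days_tested ≥ 16` (the CMS remote-monitoring
reimbursement bar), with a twice-daily variant requiring ≥ 2 tests on a
day.  Medication adherence uses greedy nearest-in-time matching of
taken to prescribed doses within ±120 min (the matching window is a
package default; each taken dose matches at most once; unmatched
prescriptions are missed).  The daily score trend is an OLS fit with
95% CI and two-sided p, requiring ≥ 3 days.  The dashboard report is a
versioned JSON document: a single-test panel of metric tiles with
normal/abnormal flags, a time-series panel, and a monthly panel with
the compliance summary.

## Problem sizes and tolerances in the test suite

Simulated checks use sizes chosen to make their statistical tolerances
meaningful at interactive cost: 40 trials for the healthy-cohort
press-amplitude recovery (±0.1 mm), 200 replicates of 26-day series for
trend recovery (±0.15 score units/day around a −1.18/day decline, noise
calibrated so the expected OLS CI half-width is 0.515), ~5,000 labelled
strikes for classifier training.  Segmentation-oracle tolerances are
±0.05 mm on amplitude and one sample period on onsets for noise-free
traces.  Sensor-noise peak-picking biases detected amplitudes upward by
about `noise_sd × E[max of plateau noise]` (~0.05 mm at the default
0.03 mm noise), which is inside the recovery tolerance and is a real
property of max-based amplitude estimation.

## Known limitations

* The age-adjustment formula adds `slope × (age − 60)` to the observed
  value; mean/SD/thresholds are computed on values adjusted the same
  way, so scoring is self-consistent, but the convention should be kept
  in mind when importing externally fitted references.
* The shipped normative pathway is simulator-based; fitting on a real
  HC cohort table is supported (`fit_reference` on any CSV with
  subject, age, hand and metric columns) and is the intended production
  route.
* Sub-sample onset interpolation is not attempted; all timing is
  quantised to the sample grid.
* The tremor classifier's feature set and thresholds are package
  choices; transferring it to real device data requires retraining on
  labelled clinical strikes.
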