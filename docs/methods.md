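# Methods

## Scope and model

fallkit implements a window-classification fall detector. The unit of
classification is a 2.5 s window of tri-axial acceleration summarized by
six statistics (per-axis mean and population variance). The classifier is a
binary RBF-kernel SVM; everything upstream (windowing, normalization) and
downstream (refractory gating, event matching, the three performance
measures) is deterministic bookkeeping specified here.

Key assumptions:

- **Uniform sampling.** Timestamps are derived from the sample index at a
  configured rate; an input time column is validated against uniformity but
  never trusted. Default analysis/simulation rate: 100 Hz, a typical value
  for wearable inertial sensors of this class.
- **Gravity included.** Signals are raw accelerometer output in g: the
  resting magnitude is ≈ 1 g and orientation changes move gravity between
  axes. No filtering, detrending or magnitude features are computed — the
  six raw-axis statistics are the entire representation.
- **Sensor saturation.** Values beyond the device range (±6 g or ±2 g) are
  clipped, never rejected, mirroring physical saturation. Clipping is
  idempotent.

## Tunable parameters

| parameter | default | unit | why |
|---|---|---|---|
| window length | 2.5 | s | long enough to span descent + impact + onset of lying |
| window overlap | 1.5 | s | 1.0 s hop bounds detection latency and alignment loss |
| C grid | 2⁻⁵ … 2¹⁵ | – | exponential sweep of the SVM regularization constant |
| γ grid | 2⁻¹⁵ … 2³ | – | exponential sweep of the RBF width |
| CV folds | 10 | – | stratified, fixed by `cv_seed` (default 0) |
| refractory | 30 | s | one alarm per physical fall; restart allows subsequent falls |
| match tolerance | ±20 | s | fall times in field data are coarse (self-report/logs) |
| sample rate | 100 | Hz | see above |
| noise SD | 0.05 | g | sensor + soft-tissue noise floor |

Grid-search ties are broken toward smaller C, then smaller γ: when several
pairs reach the same CV accuracy the least complex model is preferred. CV
accuracy is plain (unweighted) accuracy; a class-balanced alternative would
matter only for heavily skewed trial sets, and the protocol's 210/390 split
is mild.

### Training-set construction

Each laboratory trial contributes one feature vector: for fall trials the
2.5 s window centered on the sample of peak resultant deviation from 1 g
(the impact), for non-fall trials the window at the trial midpoint (each
non-fall category is constructed so its characteristic motif — gait cycle,
transition bump, postural rotation, still lying — occupies the midpoint).
An alternative mode uses every sliding window of every trial
(`build_training_set(..., mode="all")`); it multiplies the training set
size and mislabels the quiet margins of fall trials, so the single-window
mode is the default.

### Normalization

Min–max bounds are fitted on the training feature matrix only and applied
frozen at test time, clipping out-of-range values into [0, 1]. Fitting
bounds per test stream would be impossible in a streaming setting and
would let a single extreme window rescale every other. A degenerate
feature (max = min) maps to 0, avoiding division by zero deterministically.

### Detection and evaluation conventions

- An event is stamped with the start time of the triggering window; the
  refractory clock runs from that start, suppressing windows that start
  strictly within the next 30 s. Suppressed windows are logged as
  suppressed and excluded from evaluation denominators.
- Matching is greedy nearest-in-time one-to-one within the tolerance; ties
  on the time gap break by earlier detection then earlier annotation, so
  results are order-independent and deterministic.
- True negatives are counted per evaluated, non-suppressed window that is
  not fall-labeled and does not overlap any annotation ± tolerance. A
  continuous stream has no natural "discarded trial" unit, and a
  window-level denominator is the only one that makes specificity of a
  long recording well defined; it is also why specificities on long
  streams sit near 99.99% — the denominator is tens of thousands of
  windows per day.
- Reports round percentages and FP rates to 2 decimal places and print
  `n/a` where a ratio is undefined (no falls, or no negative windows).
- Pooled rows sum counts and durations across subjects before recomputing
  ratios: the pooled FP rate is (ΣFP)/(Σhours), never a mean of rates.

## The synthetic data generator

The simulator emulates two study settings: a laboratory protocol (7 fall
types, 5 near-falls, 8 ADLs; 3 trials per category per participant; 10
participants → 210 fall and 390 non-fall trials) and continuous
daily-activity monitoring with sparse embedded falls.

**Fall signature** — the canonical accelerometric morphology: quiet
pre-activity; a 0.3–0.5 s descent with the vertical magnitude dipping
toward ~0.4 g (partial free fall); a 50–150 ms half-sine impact spike of
3–5 g; then ≥ 20 s of still lying with gravity rotated 90° onto a
horizontal axis (magnitude 1 ± 0.1 g, near-zero variance). The annotation
marks the impact peak. Fall categories differ only by parameter presets
(impact range, descent speed, resting orientation), not by distinct
biomechanics.

**Near-falls** — a descent-like dip and a moderate 2–3.5 g spike, followed
immediately by resumed upright walking. They share the falls' high
acceleration but lack the impact-plus-lying conjunction, making them the
false-alarm source the trained model must reject.

**ADLs** — walking (~2 Hz vertical oscillation, amplitude ≤ 0.6 g),
quiet standing/sitting, reaching, postural transition bumps (≤ 1.8 g),
and lying-down / standing-up rotations. The rotations are deliberately
slow (2.5–4 s, realistic for older adults) in contrast to the sub-second
fall descent: an unhurried orientation change without an impact spike is
exactly the pattern the detector must not alarm on, so `lie_down` trials
place still lying and `stand_up` trials place the rotation itself at the
trial midpoint, putting both motifs in the training set as negatives.

**Continuous streams** concatenate ADL segments (weighted mix, crossfaded
over 1.5 s so activity changes look like continuous postural transitions),
with complete lying bouts (upright → rotate down → lie → rotate up →
upright on one consistent axis) so every splice joins upright signals.
Fall signatures overwrite the background at the requested instants;
requested falls must be > 60 s apart and fit inside the stream. All output
is clipped to the configured sensor range, so a 5 g impact recorded by a
±2 g device saturates at exactly 2 g.

Every generator is a pure function of (parameters, seed) using numpy's
`default_rng`; protocol trials derive their seed from
(protocol seed, participant, category, trial), making the collection
rerun-identical and order-independent.

### What the simulator does not model

No biomechanically realistic body dynamics, no gyroscope channel, no
orientation dynamics beyond a single-axis 90° gravity rotation, no
inter-subject gait variability beyond parameter ranges, no soft falls
(slides from a chair) or falls with recovery before lying. The synthetic
classes are constructed to be learnable: a pipeline that passes the
end-to-end checks here is demonstrated to be wired correctly and to learn
the impact+lying conjunction, but this says nothing quantitative about its
accuracy on real-world recordings, where class overlap is far larger.

## Numerical choices and degenerate inputs

- Window and hop lengths are converted to samples by rounding
  (window = round(2.5·rate)); only complete windows are emitted, and a
  stream shorter than one window yields no windows and no events.
- Population variance (÷ n) rather than sample variance; at 250 samples
  per window the difference is below the noise floor, but one fixed
  definition keeps every oracle comparison exact.
- Vectorized stream featurization uses cumulative sums; the variance is
  floored at 0 to absorb catastrophic-cancellation dust, and agreement
  with the per-window definition is tested to 1e-9.
- Grid search evaluates all pairs on one fixed set of stratified folds, in
  ascending (C, γ) order with strict improvement, which realizes the
  tie-break without a second pass.
- Model archives are joblib files with a format tag; loading anything else
  fails loudly.

## Problem sizes used in the checks

The shipped test-suite and acceptance runs train on the full default
protocol (600 trials, 399 grid pairs, 10-fold CV — about 15 s) and monitor
five 2-hour synthetic streams with two falls each (10 falls over 10 h).
These sizes give stable event counts while keeping a complete run near a
minute; larger streams change only the denominators, not the behavior.

## Known limitations

- Real per-category fall dynamics (trip vs. collapse vs. slip) cannot be
  inferred from summary statistics alone; the presets differ only in
  amplitude/duration ranges.
- The six mean/variance features discard spectral and temporal-order
  information; activities whose 2.5 s statistics mimic an impact-plus-
  orientation-change (e.g. throwing oneself onto a bed) would alarm.
- Whether train and test sets were historically normalized jointly or
  independently is ambiguous in this family of pipelines; fallkit freezes
  training bounds (the only option compatible with streaming) and flags
  this as a deliberate choice.
- The suppression rule means a genuine second fall within 30 s of an alarm
  is invisible by design.
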