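# Methods

## Signal model and preprocessing

A pivot-shift recording is a three-axis gyroscope trace sampled at a
nominal rate (default 100 Hz) for a few seconds while the examiner
rotates the tibia medially and flexes the knee to 90°. Analysis uses
the X axis, which reflects flexion/extension. Units are fixed to deg/s
and seconds; no unit auto-detection is attempted because phone APIs
disagree on conventions and a single convention keeps features
comparable across evaluators.

Quality control applies five explicit, configurable rules before any
feature is computed: duration within 1–10 s and at least 50 samples
(`DURATION_OUT_OF_RANGE`), no NaN samples (`NAN_SAMPLES`), less than 5%
of samples at or beyond ±2000 deg/s — a typical consumer-gyroscope
full-scale range (`SATURATION`), non-zero peak-to-peak amplitude
(`FLATLINE`), and peak |ω_x| of at least 5 deg/s so that detached or
idle captures are rejected (`AMPLITUDE_FLOOR`). Real studies discard a
comparable fraction of tests for technical failures without publishing
criteria; ours are explicit so exclusions are reproducible.

Normalization is min–max onto [0, 1], computed over the **whole** test
signal before segmentation. Normalizing per-segment would destroy
inter-segment amplitude ratios, which carry maneuver information.
Consequences: normalized features are invariant to positive affine
rescaling of the raw signal (gain differences between devices), and a
constant signal is rejected as degenerate rather than silently mapped.

Segmentation divides the trace into contiguous S1 | S2 | S3. The default
rule is equal thirds with |S1| = |S2| = ⌊n/3⌋ and the remainder going to
S3, because S3 — which contains the reduction event — is the analysis
target and should not lose samples. An explicit-boundary strategy exists
for event-aligned analyses. Segmentation always conserves samples and
order.

## Features

All standard deviations are population-normalized (ddof = 0). The
spectral slope `S3TF-P` is the OLS slope of the one-sided DFT magnitude
of normalized S3 against frequency in Hz, with the DC bin excluded: a
narrow (fast) shift lobe spreads energy to high frequencies and flattens
the spectrum, a broad lobe steepens its decay. The entropy `S3-We` is the
Shannon entropy in bits of the per-sample energy distribution
pᵢ = xᵢ²/Σxⱼ² — binning-free and deterministic, with the all-zero
segment defined as 0 bits. It measures how concentrated the segment's
energy is in time: a single sharp event gives low entropy, diffuse noise
high entropy. Class features use the normalized representation (the
"n" suffix); grade features keep raw deg/s amplitudes because absolute
angular-velocity magnitude is the laxity signal.

## Classifiers

Both classifier kinds are feed-forward MLPs: two hidden layers (32, 16),
ReLU, softmax output, cross-entropy loss, Adam (lr 1e-3, batch 32, at
most 500 epochs), per-feature z-scoring with training-set statistics
only. This is the smallest standard architecture adequate for 5–7 inputs
and at most 8 classes. A fixed seed governs initialization, shuffling
and the validation split, so training is exactly reproducible.

Early stopping (20% validation split, patience 25) is enabled only when
the validation split holds at least 50 samples. On the per-class grade
datasets (tens of rows) a 6–26 row validation split ranks epochs so
noisily that early stopping halts training long before convergence;
those fits run the full epoch budget instead. The decision threshold is
a property of the estimator, not of any particular dataset.

Grade models are fitted one per maneuver class (2–7), mirroring the
per-class grade evaluation design; classes 1 and 8 are executions
furthest from the standardized maneuver and are never graded. Prediction
ties break to the lowest class index for determinism. Models serialize
to a single JSON file (architecture, scaler statistics, weights, seed,
feature names); inference is an explicit forward pass over those arrays,
so a restored model is a pure function with no dependency on the
training stack.

When evaluating the per-class grade models, each held-out test is routed
to the grade model of its *true* class — the setting in which per-class
grade confusion matrices are defined. Deployment prediction routes by
the predicted class, and tests routed to class 1 or 8 are explicitly
marked non-gradable.

## Statistics

The per-class "accuracy" in reference confusion tables for this
instrument is arithmetically TP/(TP+FP+FN) — the critical success index,
not accuracy with true negatives. It is implemented under the name
`accuracy_paper` to reproduce printed tables without propagating a
misleading name; standard multiclass accuracy is exposed separately.

Chi-square association uses the Pearson statistic with no continuity
correction and the true upper-tail p-value. Mann–Whitney U uses midranks
for ties; the p-value is exact by enumeration when n_a + n_b ≤ 16 with
no ties, otherwise a normal approximation with tie and continuity
corrections (the result records which method was used). ROC curves sweep
thresholds over unique scores; the trapezoidal AUC equals the
pair-counting estimator with ties counting one half. The injury score is
the predicted probability of grade ≥ 1 from the routed grade model, with
ground truth grade 0 vs grades 1–3 (this choice is configurable —
published AUCs for such instruments rarely state the exact score).

## Synthetic data generator

No raw clinical recordings of this maneuver are published, so the
simulator is a documented stand-in designed to make every property of
the pipeline testable, not a biomechanical model. The X-axis waveform is

ω_x(t) = A_f·exp(−(t−t₁)²/2σ₁²) − g·Δ·exp(−(t−t₂)²/2σ₂²) + ε(t)

with flexion amplitude A_f = 60 deg/s, grade step Δ = 30 deg/s (so the
shift lobe is 0/30/60/90 deg/s deep for grades g = 0–3), sensor noise
ε ~ N(0, σ²) with σ = 3 deg/s, and Y/Z channels leak-coupled to X
(gains 0.35/0.20) plus independent noise. Default duration 3 s at
100 Hz.

Each maneuver class fixes (t₁, σ₁, t₂, σ₂) as fractions of the
recording. Classes 2–7 are standardized executions: their shift lobes
lie in the final third, and the flexion lobes sit on an evenly spread
timing/width grid (t₁ from 0.40 to 0.70 of the duration, σ₁ from 0.07
to 0.17) so that the lobe tail reaching S3 is class-distinctive even for
grade 0, where no shift lobe exists. The grid spacing is a design
requirement, not a tuning knob: with a shared morphology, grade-0 tests
of different classes would be mathematically indistinguishable in
S3-only features. Class 1 models a capture stopped mid-flexion: 30% of
the nominal duration ending on the rising lobe — it fails default QC on
duration, by construction. Class 8 models a mistimed maneuver with the
shift lobe in the middle third; it passes signal-level QC (nothing is
technically wrong with the capture) and is instead recognised — and
excluded from grading — by the class model.

Default cohort composition emulates the reference multicenter cohort:
class proportions (11, 28, 81, 79, 90, 83, 21, 6)/399 from the
standardized-test column of the observed class-frequency table; grade 0
at 83/399 (the postoperative and follow-up fraction, treated as stable
knees) with the injured remainder split 60/33/7% across grades I–III;
contexts office/preop/postop/followup at (136, 180, 63, 20)/399 and
right knees at 233/437. Context and side are drawn independently of
grade and class — a simplification; in reality context correlates with
grade.

What the simulator does **not** emulate: joint kinematics, accelerometer
channels, evaluator-specific technique drift, autocorrelated sensor
noise, or within-class morphology variance beyond the additive noise.
Passing recovery tests therefore shows that the pipeline's feature and
classification machinery is correct and well-conditioned, not that the
instrument achieves any particular accuracy on clinical data.

## Evaluation protocol and problem sizes

End-to-end recovery simulates 600 tests at the default composition,
splits 80/20 stratified jointly on (class, grade) — class-only
stratification can leave a rare cell such as class 7 × grade 0 entirely
out of training, making that grade unrepresentable for the per-class
model — and requires held-out class accuracy ≥ 0.90, grade accuracy
≥ 0.90 on classes 2–7, and injury AUC ≥ 0.90. Across ten seeds the
observed worst cases are 0.917 / 0.982 / 1.0. Statistical calibration
checks the Mann–Whitney type-I error at α = 0.05 over 1000 null
replicates of n = 50 + 50. Oracle suites compare the FFT path against a
naive O(n²) DFT (1e−9), segment statistics and regressions against
closed forms (1e−12 / 1e−9), chi-square against the textbook E-matrix
summation (1e−10), and AUC against pair counting (1e−12).

## Known limitations

* The 8 maneuver classes are taken as given labels; whatever clustering
  or expert process defined them originally is not modeled.
* Segment boundaries are time-based (equal thirds); event-based
  segmentation of real recordings would need a shift-event detector.
* The normalized-spectrum slope interpretation of `S3TF-P` is one of two
  defensible readings (the other being a time-domain slope); the choice
  is fixed and documented here.
* Per-class grade models cannot output a grade absent from their
  training rows; the jointly stratified split mitigates this in
  evaluation, but deployment on very small cohorts inherits the issue.
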