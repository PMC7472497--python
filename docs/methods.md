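# Methods

`fogkit` detects freezing of gait (FOG) in Parkinson's disease from three
body-worn inertial sensors (lower back, left ankle, right ankle; tri-axial
accelerometer and gyroscope, 128 Hz, axes vertical / anterior-posterior /
medio-lateral). This note documents the model, its assumptions, the tunable
parameters, the synthetic-data generator, and the numerical and design
choices that were genuinely open.

## Signal model and preprocessing

All channels are low-pass filtered with a second-order Butterworth filter at
15 Hz. The filter is applied forward-backward (zero phase), so the effective
magnitude response is the squared Butterworth magnitude; this was chosen
because the analysis is offline and phase distortion would shift episode
boundaries relative to the annotations. Sampling rates at or below 30 Hz are
rejected rather than resampled.

Ground-truth FOG annotations are half-open `[start, end)` intervals in
seconds. Before any windowing they are cleaned by first merging episodes
separated by less than 1 s and then deleting episodes shorter than 1 s.
Merge-before-drop is deliberate: two sub-second fragments less than a second
apart represent one fragmented real episode and survive as their union;
drop-before-merge would delete both. Cleaning is idempotent.

Analysis windows are 3 s long. Training windows are cut on two grids
anchored at trial start: a 0.6 s step (80% overlap) wherever the window is
FOG-labeled — enriching the minority class without synthetic resampling —
and a 1.5 s step (50% overlap) elsewhere. Test windows use a uniform 1.5 s
step. A window is FOG when at least 1.5 s of it overlaps annotated freezing
(boundary inclusive). Windows running past the trial end are discarded
because every spectral feature needs 3 s of real signal. Whether the
original protocol anchored FOG grids at episode onsets rather than trial
start is unknowable from the available description; trial-start anchoring is
simpler and is used for both grids.

Accelerometer units are fixed at m/s² and gyroscope at deg/s in the file
dialect, and gravity is retained (a constant 9.81 m/s² on the vertical
accelerometer axis): the spectral bands used by every frequency feature
exclude DC, and time-domain features are expected to tolerate the offset.

## Feature library

Each window yields 86 features over four sensor groups — back accelerometer,
back gyroscope, legs accelerometer, legs gyroscope. Leg-sourced features are
computed per ankle and aggregated with max (min for the two
range-of-cumulative-sum features that the final model uses in min form), so
all leg features are invariant to swapping the legs.

* Time domain (52): per group and axis, mean, SD, skewness and range of
  cumulative sum (48); tri-axial RMS per group (4).
* Frequency domain (30): per group, the freezing index plus band power,
  peak frequency and spectral entropy in the walk band (0.5–3 Hz) and the
  freeze band (3–8 Hz) on the group's designated axis (28); spectral
  skewness of the walk band for back-accel AP and back-gyro ML (2).
* Cross-sensor and inter-leg (4): the two legs-to-back RMS ratios
  (max-leg tri-axial gyro RMS over back accelerometer RMS, and over back
  gyroscope RMS), inter-leg correlation of gyro ML, and the inter-leg
  mean-magnitude min/max ratio of gyro ML.

The freezing index of a window is the integrated power spectral density in
3–8 Hz divided by that in 0.5–3 Hz of the anterior-posterior leg
acceleration, maximum over the two legs; it is always computed on the AP
axis because that is its definition, while each group's other spectral
features use one designated axis (back-accel AP, back-gyro V, legs-accel V,
legs-gyro V). The classic threshold detector labels a window FOG at FI > 2.5.

The spectral estimator is a single-segment Hann-tapered periodogram of the
384-sample window; 3 s windows are too short for multi-segment averaging.
Band integrals use the trapezoid rule on the discrete grid with inclusive
edges. Spectral entropy is the Shannon entropy (nats) of the PSD normalized
to unit sum within the band.

Degenerate inputs follow fixed conventions so that a zero window maps to a
finite, all-zero feature vector: ratios with zero denominator are 0,
correlations with a zero-variance argument are 0, the entropy of a
zero-power band is 0, and the peak frequency of a zero-power band is the
band's lower edge. Any remaining non-finite value is a hard error naming
the feature.

The comparator feature set (Samà et al.-style, back accelerometer only)
implements axis-mean differences, per-axis SD/skewness, inter-axis
correlations, skewness of the magnitude signal, band SDs and skewnesses,
the two largest spectral peaks and their separation, the spectral center of
mass, and the first three principal-component projections of the 0.04–8 Hz
spectrum. Its frequency features operate on the PSD of the mean-removed
per-sample norm of the three axes (mean removal stops gravity leakage from
dominating the harmonic features). The PCA basis is fit once on the
training-cohort windows, never at test time; a global training-set fit was
chosen over per-subject bases to keep the method patient-independent.

## Feature selection

Per training fold:

1. **Screening** — Welch (unequal-variance) t-test per feature between FOG
   and non-FOG windows, retaining p ≤ 0.05/86. Welch was preferred over the
   pooled test because the window classes are imbalanced and sensor features
   are heteroscedastic. The Bonferroni denominator stays at the full
   manifest size (86) regardless of how many features survive. Constant
   features (undefined t) are excluded.
2. **MRMR ranking** — greedy minimum-redundancy-maximum-relevance in the
   MID (difference) form: each step adds the feature maximizing
   `I(f; y) − mean I(f; s)` over already-selected `s`, with mutual
   information on equal-frequency 10-bin discretizations (features with ≤10
   distinct values keep their own codes). Ties resolve to the earlier
   column, making the trace deterministic and checkable by brute force.
3. **Count choice** — for each prefix length k of the ranking, an SVM is
   trained and scored on subject-wise 5-fold inner splits of the training
   fold; the k with minimum mean misclassification error wins, smaller k on
   ties. The inner split is subject-wise to keep the error estimate
   patient-independent, and is used instead of the held-out LOPO subject to
   avoid test leakage. The search is capped at k ≤ 20 by default; the
   observed optima sit well inside the cap and the full range remains
   available via `max_k=None`.

The final model ranks features by *commonness* — how many LOPO folds chose
them — with ties broken by mean MRMR rank and then lexicographically, picks
the count by the same inner-CV rule on the whole training cohort, and
refits on all training subjects.

## Classifier and validation

The window classifier is an SVM with RBF kernel on z-scored features
(standardization parameters from training windows only; added because RBF
kernels require comparable scales). Hyperparameters are C = 1 and
gamma = "scale"; these are defaults, not reproductions of the original
model, whose C/gamma were never reported. Class imbalance is handled solely
by the asymmetric window overlap, not by class weights.

Validation is leave-one-patient-out: each fold reruns the full selection on
the remaining subjects, trains, and scores the held-out subject's test-role
windows. Sensitivity is TP/(TP+FN) in percent, specificity TN/(TN+FP),
accuracy (TP+TN)/total; a recording with no FOG windows scores 100%
sensitivity by convention. Per-fold ROC curves (from decision-function
scores) are vertically averaged on a common false-positive-rate grid; the
optimal operating point is the mean-curve point nearest (0, 1). AUC uses
the trapezoid rule.

## Episodes and derived outcomes

Overlapping test-window predictions are fused per sample by majority vote
over the covering windows, ties counting as FOG (favoring sensitivity —
with the 1.5 s test step interior samples are covered by exactly two
windows, so the tie rule decides every disagreement). The binary timeline
becomes intervals, which pass through the same merge/drop cleaning as the
annotations so predicted and true episode sets are directly comparable
objects. Derived outcomes are percent time frozen (100 × total frozen time
/ trial duration), total frozen time, and episode count.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable without
clinical data. It emulates the spectral structure that the detector
exploits, not biomechanics:

* **Walking** — cadence sinusoid (default 1.8 Hz, per-subject jitter
  SD 0.15 Hz) plus a first harmonic at 0.3 relative amplitude on all sites;
  trunk amplitude comparable to leg amplitude.
* **Trembling FOG** — per-subject tremor frequency drawn uniformly in
  3.5–7.5 Hz on the legs, with trunk amplitude scaled by a dissociation
  factor of 0.08 (forward body movement collapses while the legs
  oscillate — the behavior that motivates the legs-to-back RMS ratio
  features).
* **Akinetic FOG** — near-zero movement above sensor noise. These are the
  designed hard cases against quiet standing.
* **Quiet standing** — low-frequency postural sway (0.3 Hz, 0.06 m/s²),
  present in any real standing human and the only cue separating standing
  from akinetic arrest.

Episodes per trial are Poisson (mean 3) with log-normal durations (median
~4.5 s, σ = 0.5, truncated to ≥1.2 s and ≤20 s), akinetic with probability
0.2, scheduled with ≥1.2 s inter-episode gaps so the generated ground truth
is stable under annotation cleaning (a `dirty` mode relaxes the minima to
exercise the cleaner). State changes are smoothed with 0.2 s raised-cosine
cross-fades; white noise (0.05 m/s², 1.5 deg/s) is added everywhere, and
gravity rides on the vertical accelerometer axis. The annotation track
covers exactly the trembling and akinetic samples.

Default cohort: 25 subjects × two 40 s trials (about half an hour of
signal), split 80/20 into training and test subjects — a desk-scale cohort
on which the full experiment, including per-fold selection, runs in a few
minutes on one CPU. Amplitude defaults were fixed once so that trembling
windows exceed the FI = 2.5 threshold and walking windows stay well below
it, and are not physically calibrated; real-data amplitude scales are
unknown.

What passing on this generator does **not** show: robustness to real-world
gait variability (turning, doorways, festination), sensor misalignment or
drift, annotation noise, or truly ambiguous akinetic-versus-standing
segments (the simulated sway cue is cleaner than reality). Results on the
synthetic cohort demonstrate correctness of the machinery and recovery of
planted spectral structure, not clinical performance.

## Reproducibility

All randomness derives from one root seed fanned out through named,
CRC-stable substreams (`simulate`, `split`), so stages are independently
reproducible and a rerun with the same seed yields byte-identical reports.
SVM training is deterministic given its inputs.

## Known limitations

* The exact composition of the original 86-feature list is not fully
  published; the manifest here spans every named feature family and
  reproduces all 14 final-model features, and would be superseded by a
  complete published listing.
* Episodes shorter than ~1.5 s are undetectable by construction (3 s
  windows with a 1.5 s overlap rule).
* The window-fusion rule for overlapping test predictions is not described
  in the source protocol; per-sample majority vote with FOG ties is this
  package's choice.
* Hyperparameters, standardization and the inner count-selection split are
  package choices where the original protocol is silent; headline clinical
  numbers are not expected to reproduce on synthetic data.
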