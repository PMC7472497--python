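# fogkit

Automated detection of freezing of gait (FOG) from wearable inertial
sensors, for researchers quantifying FOG severity in Parkinson's disease.

FOG is an episodic inability to produce effective stepping — either
*trembling* (the legs oscillate at 3–8 Hz without forward progression) or
*akinetic* (total movement arrest). Clinical assessment relies on
video-annotated FOG-provoking tests; `fogkit` implements the automated
alternative: a patient-independent window classifier over signals from
three inertial sensors (lower back and both ankles, tri-axial accelerometer
+ gyroscope at 128 Hz), from raw signals to episode-level outcomes.

## Method

1. **Preprocess** — zero-phase 2nd-order Butterworth low-pass at 15 Hz;
   annotation cleaning (merge episodes <1 s apart, drop episodes <1 s).
2. **Window** — 3 s windows; training grids with 80% overlap inside FOG
   regions and 50% elsewhere (class enrichment), test grid at 50% overlap.
   A window is FOG iff ≥1.5 s overlaps annotated freezing.
3. **Features** — 86 per window across back/leg accelerometer and
   gyroscope groups: per-axis moments and range of cumulative sum,
   tri-axial RMS, band powers, peak frequencies and spectral entropies in
   the walk (0.5–3 Hz) and freeze (3–8 Hz) bands, the freezing index

       FI = ∫₃⁸ PSD(f) df / ∫₀.₅³ PSD(f) df   (AP leg accel, max over legs),

   inter-leg gyro-ML correlation and mean-magnitude ratio, and the two
   legs-to-back RMS ratios that capture trunk-leg dissociation during
   trembling FOG.
4. **Select** — per fold: Welch t-test screening with Bonferroni (α =
   0.05/86) → greedy MRMR ranking (mutual-information difference scheme) →
   feature count by minimum subject-wise inner-CV misclassification error.
5. **Classify** — SVM-RBF on z-scored features; leave-one-patient-out
   (LOPO) validation; a final model trained on all training subjects using
   the commonness ranking of the per-fold selections; evaluation on a
   disjoint test cohort.
6. **Episodes** — per-sample majority vote over overlapping window
   predictions → cleaned episode intervals → percent time frozen, total
   frozen time, episode count.

Two comparators are built in: the classic freezing-index threshold detector
(FOG iff FI > 2.5) and a back-sensor-only feature set fed to the same SVM.
A synthetic cohort generator (walking / trembling / akinetic / standing
states with scheduled ground-truth episodes) makes the whole pipeline
testable without clinical data — see `docs/methods.md`.

## Worked example

```python
from fogkit import (ExperimentConfig, run_experiment, compare_methods)

report = run_experiment(ExperimentConfig(seed=1))
mm = report.lopo.mean_metrics()
print(f"LOPO  acc {mm['mean_accuracy']:.1f}%  sens {mm['mean_sensitivity']:.1f}%  "
      f"spec {mm['mean_specificity']:.1f}%  AUC {mm['mean_auc']:.2f}")
tm = report.test_metrics
print(f"test  acc {tm.accuracy:.1f}%  AUC {tm.auc:.2f}")
print(f"percent-time-frozen Spearman r = {report.spearman_percent_tf:.2f}")
```

prints, for the default synthetic cohort (25 subjects, 20 train / 5 test):

```
LOPO  acc 95.5%  sens 98.6%  spec 93.0%  AUC 0.99
test  acc 98.0%  AUC 1.00
percent-time-frozen Spearman r = 0.98
```

LOPO accuracy is the mean over the 20 held-out training subjects; the test
row is the final model applied to the 5 never-seen subjects; the Spearman
correlation compares predicted and ground-truth percent time frozen across
the 10 test trials. On the same cohort the freezing-index threshold
detector reaches 92.0% mean accuracy versus 95.5% for the full pipeline.

The same experiment is available from the shell:

```sh
fogkit run --seed 1 --out report.json
fogkit simulate --seed 4 --out cohort/          # write a cohort to disk
fogkit windows --role test --trial cohort/S00/trial_00 \
       --annotations cohort/S00/trial_00/annotations.json --out w.json
fogkit features --trial cohort/S00/trial_00 --windows w.json --out f.csv
```

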