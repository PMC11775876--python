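# ahrkit

**Accelerometer-based additional heart rate (aHR) estimation for
ambulatory stress research.**

Heart rate responds to mental stress — but in daily life it responds far
more to movement, posture and recent exercise, which makes raw HR nearly
useless as a stress signal outside the lab. `ahrkit` implements the
*additional heart rate* approach: predict the movement-related part of
heart rate from hip-worn triaxial accelerometry, and read the residual as
a candidate stress signal. It is aimed at psychophysiologists and wearable
-signal researchers who want a complete, inspectable reference pipeline:
signal conditioning, hierarchical activity recognition, per-subject
lagged regression, and the validation analyses — plus a synthetic-data
generator with full ground truth, since no public dataset exists for this
method.

## The model

Acceleration is conditioned (4th-order 5-Hz low-pass Butterworth,
decimated 1000 → 100 Hz), gravity-corrected (0.1-Hz high-pass, for the
vector magnitude VM only), and aggregated into non-overlapping 30-s
windows; 6-s / 50%-overlap epochs feed a hierarchical classifier (linear
SVM static/dynamic gate → boosted-tree posture model → convolutional
activity-type model) evaluated leave-one-subject-out. Per subject *i*,
four nested OLS models predict the window heart rate, the richest being

  pHRᵢ = β₀ + β₁·VMᵢ + Σⱼ βⱼ·Aᵢⱼ + β₈·(1/6)Σₜ₌ᵢ₋₆..ᵢ₋₁ VMₜ + εᵢ

with activity-class dummies Aᵢⱼ (lying as reference) and a 3-minute lagged
VM term for post-exercise recovery. Fits use 5-fold cross-validation so
every window's predicted HR (pHR) is out-of-sample. Then

  aHR = oHR − pHR

is the movement-unexplained residual. Validation compares aHR against
classic task-baseline reactivity (ΔHR) between subjects, and tests
whether the top-30% of a subject's aHR values coincide with scheduled
stress conditions better than the top-30% of raw oHR does.

## Worked example

Simulate a 10-subject cohort on the packaged 26-condition protocol, fit
all four HR models, and run the stress-detection comparison:

```python
import pandas as pd
from ahrkit import schedules, synth
from ahrkit.hrmodel import fit_subject_all_models, compare_models
from ahrkit.ahr import compute_ahr, compute_delta_hr, within_subject_detection

schedule = schedules.study2_schedule()          # 26-condition lab protocol
cohort = synth.generate_cohort(10, schedule, seed=1, level="windows")

frames, metrics = [], []
for subject in cohort.subjects:
    per_model, met = fit_subject_all_models(subject.windows, seed=subject.seed)
    frames.append(per_model[4])                 # windows with held-out pHR
    metrics.append(met[["subject", "model_id", "adj_r2", "rmse_bpm"]])

metrics = pd.concat(metrics, ignore_index=True)
print(metrics.groupby("model_id")[["adj_r2", "rmse_bpm"]].mean().round(3))

comparison = compare_models(metrics, alpha=0.025)
print(comparison.table[["pair", "metric", "t", "p", "significant"]].round(3))

windows = compute_delta_hr(compute_ahr(pd.concat(frames, ignore_index=True)),
                           schedule)
for signal in ("ahr", "ohr"):
    rep = within_subject_detection(windows, signal=signal)
    print(f"{signal}: recall={rep.summary['recall_mean']:.2f} "
          f"precision={rep.summary['precision_mean']:.2f}")
```

Output:

```
          adj_r2  rmse_bpm
model_id
1          0.702    12.366
2          0.744    11.354
3          0.830     9.109
4          0.954     4.431
  pair    metric       t    p  significant
0  2v1    adj_r2   8.985  0.0         True
1  2v1  rmse_bpm -10.387  0.0         True
2  3v2    adj_r2   7.627  0.0         True
3  3v2  rmse_bpm  -9.926  0.0         True
4  4v3    adj_r2  15.875  0.0         True
5  4v3  rmse_bpm -16.841  0.0         True
ahr: recall=0.66 precision=0.74
ohr: recall=0.00 precision=0.00
```

Reading it: each added predictor group — posture, activity type, lagged
VM — raises the cross-validated adjusted R² and lowers the RMSE of HR
prediction, all improvements significant at α = 0.025. Movement-corrected
aHR recovers about two thirds of the scheduled stress windows, while raw
oHR recovers none: the stress tasks sit (literally) at low heart rates
next to exercise conditions, so the highest raw-HR windows are all
exercise.

The same stages are available from the shell, chained through CSV files:

```bash
ahrkit simulate --n-subjects 10 --schedule demo --level raw --seed 1 --out-dir out/sim
ahrkit preprocess --accel out/sim/s000_accel.csv --beats out/sim/s000_beats.csv \
       --schedule out/sim/schedule.csv --subject s000 --out-dir out/pre
ahrkit train-activity --data-dir out/sim --seed 1 --out-dir out/act
ahrkit fit-hr --windows out/act/windows.csv --seed 1 --out-dir out/fit
ahrkit ahr --windows out/fit/windows_phr.csv --schedule out/sim/schedule.csv --out-dir out/ahr
ahrkit validate-within  --windows out/ahr/windows_ahr.csv --out-dir out/val
ahrkit validate-between --windows out/ahr/windows_ahr.csv \
       --schedule out/sim/schedule.csv --out-dir out/val
```

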