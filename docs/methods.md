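# Methods

`ahrkit` implements an accelerometer-based estimate of *additional heart
rate* (aHR): the part of heart rate that movement cannot explain, read as a
mental-stress signal. This note documents the model, the processing
choices, the synthetic-data generator, and the numerical conventions, in
the order the pipeline runs.

## Signal conditioning

Raw triaxial acceleration (hip-worn device convention: x anterior-
posterior, y vertical, z mediolateral; units g; nominally 1000 Hz) is
low-pass filtered with a 4th-order 5-Hz Butterworth and decimated to
100 Hz. For the vector magnitude (VM) only, a 4th-order 0.1-Hz high-pass
is applied to a copy of the raw signals first, removing the gravity
component; the per-axis classification features deliberately keep gravity,
because the orientation of the gravity vector encodes posture.

Choices the underlying method leaves open, fixed here:

- **Zero-phase filtering.** All filters run forward-backward
  (`sosfiltfilt`), so the VM stays time-aligned with the heart-rate
  windows; causal filtering would shift the VM by the group delay. The
  0.1-Hz high-pass has ~10-s edge transients; analyses that care (e.g. the
  static-recording VM contract) skip the first seconds.
- **Antialiasing decimator.** An 8th-order Butterworth at 0.8x the new
  Nyquist (40 Hz), zero-phase. A maximally flat design keeps the passband
  — notably DC, i.e. gravity — at exactly unit gain; a rippled Chebyshev
  decimator would scale constant signals by its ripple factor (~1.1% for a
  0.05-dB design applied forward-backward), which matters because gravity
  components feed the posture features.
- **VM formula.** Per-sample Euclidean norm sqrt(x²+y²+z²)
  (`vm_mode="norm"`); a root-mean-square variant (norm/sqrt(3)) is exposed
  as `vm_mode="rms"`. The two differ by a constant that the VM slope
  coefficients absorb, so nothing downstream depends on the choice.

## Segmentation

Classification operates on 6-s epochs overlapping by 50% (starts at 0, 3,
6, ... s; `floor((T-6)/3)+1` epochs in a T-second recording). Analysis
operates on non-overlapping 30-s windows. An epoch belongs to the window
containing its start time, which gives exactly ten epochs per fully
covered window; the window label is the majority vote over its epochs,
with ties broken by a fixed class priority (lying < sitting < standing <
walking < jogging < cycling < stairs) and recorded in a `tie` flag.
Condition labels, stress and baseline flags come from the protocol
schedule at the window midpoint; windows in between-condition gaps carry
no condition and are excluded from analyses.

## Heart rate

Beat series arrive as R-peak times (ms). Deviant intervals are flagged
when |IBI − local mean| > k·(local SD), over a centred window of
`local_n = 20` intervals excluding the interval itself, with `k = 3.0`
(short series fall back to global statistics). The original recording
software's thresholds are unpublished; these defaults follow standard HRV
artifact-screening practice and the rule is deliberately simple and
deterministic. Runs of up to 3 flagged intervals are linearly interpolated
between the neighbouring valid intervals; longer runs (or runs touching
the series boundary) are excluded. Window heart rate is
60000 / mean(IBI ms) over the intervals whose end beat falls in the
window (`hr_mode="rate_mean"` averages 60000/IBI instead); windows with
fewer than 10 usable intervals are HR-invalid and dropped.

## Activity recognition

A three-stage hierarchy, all trained under leave-one-subject-out
cross-validation (LOSO): for each held-out subject the remaining subjects
are split 90%/10% *at the subject level* (seeded, unstratified) into
training and validation sets, so no tuning decision ever sees data from
the held-out subject or from a subject in both roles.

1. **Static/dynamic gate** — linear SVM on 36 standardized epoch features
   (per axis: mean, max, min, range, variance, SD, skewness, kurtosis,
   inclination, zero-crossing rate; VM mean/variance/SD; pairwise axis
   correlations). The cost parameter is picked from the integer grid
   2..16 by 5-fold cross-validated accuracy (ties to the smaller cost).
   Feature conventions: population moments, kurtosis as excess kurtosis;
   inclination = arccos(mean_axis / ‖mean vector‖); zero-crossing rate on
   the mean-centred signal, per second; degenerate (constant) axes return
   0 for skewness/kurtosis/correlation.
2. **Posture classifier** (lying / sitting / standing) — XGBoost over the
   same features, hyperparameters searched by a seeded tree-structured
   Parzen estimator over max_depth 2–6, gamma 0.5–10, eta 0.05–0.3,
   reg_alpha 1–50, reg_lambda 1–10, subsample 0.8–1, colsample_bytree
   0.5–1, min_child_weight 0–10; budget = 10 evaluations per
   hyperparameter (80); objective = weighted F1 on the validation
   subjects. The TPE (`ahrkit.bayesopt`) uses the adaptive Parzen
   estimator: per-point bandwidths from neighbour spacing plus a full-span
   prior component at the box centre — without the prior component the
   density ratio collapses onto the incumbent and stops exploring.
   `n_estimators` is fixed at 50 (not part of the published search space).
3. **Dynamic-type classifier** (walking / jogging / cycling / stairs) — a
   small 1-D convolutional network over the raw 600x3 epoch samples
   (channel-standardized with training statistics): two blocks of
   [conv(16/32 filters, kernel 9) + ReLU + max-pool 4], global average
   pooling, dense softmax. SGD with learning rate 0.01, per-update decay
   1e-4, Nesterov momentum 0.9, at most 100 training epochs ("iterations"
   read as epochs), batch size 32. Implemented directly in NumPy
   (float32), deterministic given its seed. The classifier slot is
   pluggable: anything exposing `fit`/`predict` over epoch arrays can
   substitute.

Metrics are per-subject accuracy and weighted precision/recall/F1
(weights = true-class support within the subject, because class
availability varies between subjects), summarised as mean ± SD across
subjects, plus a confusion matrix row-normalised by true-class occurrence.

## Movement-related heart rate: four nested models

Per subject, ordinary least squares of the 30-s mean heart rate on:

| Model | Covariates |
|---|---|
| 1 | VM |
| 2 | VM + posture (sitting, standing; lying = reference) |
| 3 | VM + 6 activity-class dummies (lying = reference) |
| 4 | Model 3 + lagged VM (mean VM of the 6 preceding windows) |

In Model 2 every window contributes its *underlying posture*: walking,
jogging and stair-walking are upright (standing); ergometer cycling is
seated (sitting). The lag length of 6 windows (3 min) trades capturing
post-exercise recovery against losing the first 6 windows of each
recording, which are lag-invalid and removed before fitting Model 4.

Each subject is fitted with seeded 5-fold cross-validation: 80% of
windows fit the model, the held-out 20% receive predictions (pHR), so no
window is predicted by a model that saw it. Coefficients are reported as
fold means alongside a full-data refit. Two rank-deficiency cases are
handled by deterministic column dropping (logged): an activity class
absent from a training fold loses its dummy, and if the lying reference
class is absent (it can be — the long protocol places lying only in the
lag warm-up) the first remaining dummy is folded into the intercept.
Stress windows are *included* in fitting but *excluded* from the adjusted
R² and RMSE, which are computed on held-out predictions with p = the
nominal covariate count (1/3/7/8) — the adjustment is nominal because the
predictions are out-of-sample; both toggles are exposed. Consecutive
models are compared across subjects with two-sided paired t-tests on
adjusted R² and RMSE at alpha = 0.05/2 = 0.025 (two metrics).

## aHR, classic reactivity, validation

aHR = oHR − pHR, per window, bit-exact by construction. Classic
reactivity ΔHR subtracts instead the mean HR of the posture-matched
baseline condition(s) (two baselines per posture average their condition
means); windows in unknown gaps get ΔHR relative to their own gap mean,
flagged `visualization_only` and excluded from analyses.

Between subjects: per stress condition, the Pearson correlation between
subject-mean aHR and subject-mean ΔHR (undefined below 3 subjects or at
zero variance), with scatter points, identity line and centroid.

Within subjects: the top 30% of a subject's valid experimental-condition
windows by signal value are declared "stress" and scored against the
scheduled stress flag — the 30% mirrors the share of stress time in the
long protocol. The cut count is round(0.30·n); ties at the threshold are
included earlier-window-first (deterministic). Confusion matrices are
row-normalised by true-class occurrence; subjects without any stress
window are excluded from stress-class averaging and logged. The same rule
applied to raw oHR is the comparison condition. The threshold is computed
over experimental-condition windows only, consistent with the ground-truth
definition; a toggle widens it to all windows.

## Synthetic-data generator

No public dataset exists for this method, so `ahrkit.synth` generates
coupled accelerometer + heartbeat recordings with known ground truth.

**Kinematics.** Acceleration = gravity orientation (lying along −x,
sitting tilted ~35° in the x–y plane, standing along −y; dynamic classes
standing-oriented) + class-specific oscillation (walking 2.0 Hz / 0.4 g,
jogging 2.8 Hz / 0.9 g, stairs 1.8 Hz / 0.6 g with enlarged vertical
variance, cycling 1.4 Hz / 0.15 g, spread over axes with fixed phase
offsets) + white noise (0.015 g static, 0.05 g dynamic). The oscillation
amplitude is slowly modulated (±25%, 75-s period, random phase) so the
window VM varies *within* each activity class — without this, VM would be
collinear with the class dummies and the regression unidentifiable at low
noise. Raw output is 1000 Hz so the full decimation chain is exercised.

**Cardiac ground truth.** Window-level true HR follows the Model-4
structure with generating coefficients (69.1, 36.0 BPM/g; sitting +12.9,
standing +19.8, walking +18.6, jogging +22.6, cycling +33.7, stairs
+34.3 BPM; lagged VM 58.6 BPM/g), plus `stress_effect` (default +10 BPM,
optionally drawn per subject from a uniform range) during scheduled
stress conditions, plus AR(1) noise (coefficient 0.6, innovation SD
2.4 BPM, stationary SD ~3 BPM). Subject-level random effects around these
defaults use SDs (8, 6, 2, 2, 3, 4, 4, 4, 8) — deliberately smaller than
the between-subject SDs of *fitted* coefficients one would see in real
cohorts (those include estimation noise), so that every simulated subject
keeps physiologically sensible positive slopes. Heartbeats are emitted by
integrate-and-fire over the piecewise-constant window rate; windowed beat
rates match the true HR within 1 BPM (a discretisation contract — the
interval spanning a window boundary carries the previous window's rate,
so beat-derived HR is not exact beyond that bound, and exact-recovery
tests read oHR from the generating truth instead).

**Two granularities.** `generate_subject` emits full raw recordings;
`generate_windows` emits the analysis-ready window table directly (class
VM levels chosen near what the raw path produces), for regression and
detection studies where the signal chain is not under test.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sensor calibration error and drift, gait
individuality and within-class posture variety, ectopic-beat morphology,
respiratory sinus arrhythmia, circadian drift, and the ergometer failure
mode (cycling workload rising without movement-intensity change; the
generator is faithful to the Model-4 structure by design, so aHR's known
blind spot to workload-without-movement is out of its scope — it can be
emulated by adding an offset to true HR during cycling).

## Problem sizes

The packaged benchmarks run at desk scale on one CPU: activity
recognition uses 10 raw-signal subjects on a compact 11-condition protocol
(60 s per condition, all seven classes, stress tasks at rest and directly
after exercise); regression analyses use 10–20 window-level subjects on
the full 26-condition protocol (~88 min, 177 windows); parameter-recovery
studies use 242-window subjects built by repeating the compact protocol
(which keeps the lying reference class identifiable past the lag
warm-up). These sizes are the package's defaults for reproducible
examples; all of them scale up through the same interfaces.

## Known limitations

- The deviant-beat rule is a documented stand-in for unpublished
  screening thresholds; its defaults matter only for noisy beat series.
- Out-of-sample adjusted R² has no canonical definition; the nominal-p
  convention used here slightly flatters larger models at small n.
- The 90/10 tuning split is unstratified; with very small cohorts the
  validation subject may lack a class (posture tuning then errors).
- aHR inherits the method's structural blind spots: workload without
  movement (ergometry, isometric load) and baseline-shift effects — a
  fitted intercept inflated by post-exercise recovery sitting depresses
  aHR everywhere else, which the detection analyses reproduce.
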