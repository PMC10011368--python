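# Methods

This note documents the models behind `rap`: the virtual-patient
simulator, the feature/label construction, the detection network and its
training recipe, the alerting and dosing policy, and the evaluation
metrics — along with the assumptions, defaults, numerical choices and
limitations a user should know before trusting results on real data.

## Virtual-patient simulator

### Dynamics

Each subject is a minimal-model glucoregulatory system. Carbohydrate from
a meal of D grams passes through a two-compartment gut chain with equal
time constants τ_m, giving the appearance rate

    Ra(t) = D · (t/τ_m²) · exp(−t/τ_m)   [g/min],

and subcutaneous insulin (boluses) passes through an identical chain with
time constant τ_i. Because these chains are linear, their impulse
responses are evaluated analytically and summed over events; only plasma
glucose is integrated:

    dG/dt = −s_G (G − G_f) − k_I (R_i(t) − R_b) + k_C Ra(t)

with fixed-step RK4 at 1 min. Here s_G is glucose effectiveness
(fractional return toward the fasting level G_f), R_i the insulin
appearance rate, R_b = basal/60 its steady-state value, k_I the
insulin gain (mg/dL per U, the subject's `insulin_sensitivity`), and
k_C = k_I / CR the carbohydrate gain — chosen so that a meal bolused
exactly at grams/CR is glucose-neutral in integral, which is what a
correct carbohydrate ratio means. With no meals and matched basal the
system sits exactly at G_f. Plasma glucose is floored at 20 mg/dL (the
model has no counter-regulation); a non-finite state aborts with the time
index.

The CGM is a pure transport delay (default 10 min, population range
5–15 min) plus i.i.d. Gaussian noise (default SD 5 mg/dL), sampled every
5 min and clamped to the sensor range [39, 401] mg/dL.

### Calibration

The one dynamical fact the detection problem hinges on is how soon a meal
becomes visible in the CGM. The simulator is calibrated so that a 50 g
unbolused meal produces a +10 mg/dL CGM rise with a population median lag
of 20 min (range 15–30 min): s_G = 0.02/min and τ_m ~ N(28, 5) min
(clipped to 20–45). This also places the postprandial CGM peak near
80–90 min and largely resolves excursions within 3–4 h, as real traces
do. Slower clearance values produce hours-long quasi-linear rises whose
late tails are indistinguishable from meal onsets — an unrealistic
failure mode that inflates false alarms.

### Population and meals

Subject parameters are drawn independently per subject from
`(rng_seed, subject_index)` streams: carbohydrate ratio U(6, 15) g/U,
correction factor U(30, 60) mg/dL/U, insulin gain = correction factor
± 10%, basal U(0.6, 1.4) U/h, fasting glucose U(100, 150) mg/dL,
τ_i ~ N(55, 8) min. These ranges are ordinary adult type 1 diabetes
therapy settings; they are an invented population, not a reconstruction
of any proprietary simulator's cohort.

Meals occur at 08:00, 12:30 and 18:30 with N(0, 30 min) jitter. Sizes are
normal — 46.6 ± 27.1 g (low-carb diet) or 72.5 ± 29.3 g (high-carb);
under a mixed diet each subject is assigned one diet at random —
truncated at 10 g. Truncating at 10 g would lift the mean (to ≈51.4 g
for the low-carb parameters), so the location parameter is solved
numerically so that the *post-truncation* mean equals the configured diet
mean. Each meal is independently unbolused with probability 0.33
(per-meal Bernoulli; a per-subject alternative would concentrate
positives in fewer subjects). The stand-in controller delivers constant
basal and, for announced meals only, a bolus of exactly grams/CR at
mealtime. A per-meal `absorption_multiplier` can slow individual meals
(high-fat emulation); it is off by default.

## Features and labels

Predictions are made every 5 minutes from a 24-sample (2 h) CGM window
plus the insulin record. The 32-feature schema is frozen and versioned in
`features.FEATURE_NAMES`: trailing means (30/60/90/120 min), endpoint
rates of change (10/20/30/60 min), last value, range, area above the
window-start baseline, first/second difference statistics, run length of
consecutive rises, insulin on board at t/t−30/t−60 and its 1-h delta,
bolus and basal units in the window, minutes since last bolus (capped at
240), the cyclic hour pair, window SD, last-minus-hour-mean, the position
of the steepest rise, fraction of samples above 140 mg/dL, the value an
hour ago, and the baseline. Insulin on board uses a bilinear decay
kernel R(x) = 1 − x over a 240-min duration of insulin action — monotone,
bounded, zero-tailed, which is all the detector needs from it.

A prediction time is labeled positive iff an unannounced, non-rescue meal
started within the preceding 60 min; the class label is that meal's
carbohydrate bin. Announced meals and rescue carbohydrates are negatives
— the clinical target is missed-bolus detection. If two unannounced meals
share a horizon the most recent wins (logged). Windows with CGM gaps are
rejected upstream rather than imputed.

## Network and training

Architecture: 32 → 512 → 32 → 16 shared ReLU layers, then 16-unit ReLU
branches to a logistic detection unit and a 5-way softmax. Xavier-uniform
weights, zero biases, Adam at constant 1e-4, batch 128, L1 penalty 1e-6
on all weight matrices, equally weighted losses, early stopping (patience
10 epochs on a 15% stratified validation split, best weights restored,
max 200 epochs). Features are z-scored with training-split statistics
persisted in the model artifact. The implementation is plain numpy; the
backward pass is verified against finite differences in the test suite.

Two deliberate choices:

- The classification loss is computed on meal-positive samples only,
  inverse-class-frequency weighted and multiplied by (1 + 0.25·class), so
  that mass sits on larger-carb truths and underestimation is preferred
  to overestimation.
- The detection loss is *unweighted* binary cross-entropy. With ~4%
  positive windows it is tempting to re-weight positives, but doing so
  inflates the probability scale and an absolute alert threshold such as
  0.86 stops meaning "86% posterior confidence" — in our experiments a
  balanced re-weighting produced a false discovery rate above 70% at that
  threshold. A `pos_weight` knob exists for users who want a different
  operating point.

## Policy

Alerts fire at the first up-crossing of 0.86, with a 90-min refractory
period and a 60-min suppression window after reported rescue
carbohydrates (both configurable; both invented defaults). The presumed
meal time is the alert time minus 25 min — the mean in-silico detection
delay — which makes an immediately acknowledged alert dose 75% of nominal
meal insulin under the 1%-per-minute discount. Class ties resolve toward
the larger class; the dose is capped at `max_bolus` (default 10 U) as the
safety rail. Bin representatives are midpoints (10/30/50/70/90 g).

## Metrics

Alerts are matched to unannounced meals greedily in time order: an alert
claims the most recent unmatched meal within the preceding 120 min.
Sensitivity = TP/meals, FDR = unmatched alerts/alerts, detection time =
meal start → alert, all with exact Clopper–Pearson 95% intervals (beta
quantiles, verified against direct tail inversion). iAUC truncates
below-baseline increments at zero (standard incremental-AUC convention)
and integrates by trapezoid in mg·h/dL. TIR counts 70 and 180 mg/dL as
in range; TAR/TBR are strict. LBGI uses
f(g) = 1.509((ln g)^1.084 − 5.381), risk 10 f² for f < 0, averaged over
samples; it is zero above ≈112.7 mg/dL and ≥5.0 flags elevated
hypoglycemia risk.

## In-silico experiment

`experiment.run_insilico_experiment` derives all stage seeds from one
global seed, simulates the cohort, holds out 25% of *subjects* (never
windows — a subject's meals must not leak across the split), trains on
the rest, and scores the held-out subjects. The default desk-scale
problem size is 30 subjects × 14 days (~121k prediction windows, ~2 min
on one CPU); the reference protocol's 199 subjects is a configuration
change, not a code change.

At this scale and seed 1 the held-out results are: sensitivity 96.6% for
40–80 g unannounced meals (n = 59), mean detection time 28.2 ± 10.2 min,
FDR 2.9% (103 alerts). Sensitivity and detection time sit where the
reference in-silico figures do (79.0–90.0% and 27.5 ± 4.8 min); the FDR
is *lower* than the reference 10% — see limitations.

## Limitations

- The synthetic cohort is clean: boluses are exact and perfectly timed,
  there are no snacks, rescue carbohydrates, exercise, circadian insulin
  sensitivity, sensor dropouts, compression artifacts or carb-counting
  error. Detection is therefore easier than on real data — most visibly
  in the false discovery rate, which comes out at 0–3% rather than ~10%:
  almost nothing in this world produces a meal-like rise except a meal.
  Passing tests show the pipeline is correct and well-calibrated on its
  stated dynamics, not that these accuracy figures transfer to patients.
- The minimal model has no counter-regulation and a hard 20 mg/dL floor;
  hypoglycemia metrics (TBR, LBGI) are structurally mild.
- The 32-feature schema implements every named feature of the method
  (means, rates of change, insulin availability, cyclic hour) and fills
  the remainder with standard CGM shape statistics; it is isolated behind
  one versioned module so an alternative schema can be swapped in.
- The background controller is basal + announced boluses, not a model
  predictive controller; detection operates on unannounced meals
  regardless of the background controller, but glycemic outcome levels
  would differ under MPC.
- Single alerts only: the system does not re-alert if unacknowledged.
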