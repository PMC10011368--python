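# rap — automated meal detection and dosing for closed-loop insulin delivery

People with type 1 diabetes on hybrid closed-loop ("artificial pancreas")
systems still have to announce meals and bolus for them manually. Missed
announcements are common and drive most postprandial hyperglycemia. `rap`
implements the meal-handling layer of a robust artificial pancreas: it
watches the continuous glucose monitor (CGM) and insulin history, detects
unannounced meals, estimates how large they were, and recommends a
late-but-safe partial meal bolus. It also ships the in-silico
virtual-patient harness used to validate the algorithm before any clinical
use.

The package is aimed at closed-loop algorithm researchers: everything is a
plain Python library (numpy/scipy/pandas) with a thin `rap` CLI on top, and
every stage is reproducible from a single seed.

## The method

**Detection and estimation.** Every 5 minutes, the two-hour history of CGM
and insulin is summarised as 32 features (glucose level/trend/shape
statistics, insulin-on-board from a bilinear-decay kernel, dosing history,
and a cyclic encoding cos(2πh/24), sin(2πh/24) of the hour of day). A
multioutput fully connected network — shared hidden layers of 512, 32 and
16 ReLU units, then a 16-unit branch each for meal detection (logistic) and
carbohydrate class (5-way softmax over [0,20), [20,40), [40,60), [60,80),
80+ g) — maps the features to a meal probability `p` and a class
distribution. Training uses Xavier-uniform initialisation, zero biases,
Adam at a constant 1e-4, mini-batches of 128, L1 penalty 1e-6, equally
weighted binary and categorical cross-entropy (the class loss is computed
on meal-positive samples only, inverse-frequency weighted with an
asymmetry factor that penalises overestimation), and early stopping. A
meal alert fires when `p` first crosses the threshold P_TH = 0.86.

**Dosing.** Because the bolus arrives after the meal, only a fraction of
the nominal meal insulin (class-representative grams ÷ carbohydrate ratio)
is recommended: the fraction falls by 1% for every minute since the
presumed meal time (alert time − 25 min, the mean in-silico detection
delay), so an immediately acknowledged alert doses 75%:

    units = max(0, 1 − 0.01·Δt) × grams_est / CR

e.g. a detected 30 g meal with CR = 10 g/U acknowledged immediately →
0.75 × 30/10 = **2.25 U**.

**Validation harness.** A minimal-model virtual patient (two-compartment
gut absorption and subcutaneous insulin kinetics forcing a single glucose
ODE, RK4 at 1 min; CGM = 10 min transport delay + Gaussian noise, 5-min
samples clamped to [39, 401] mg/dL) generates cohorts with the study's
statistics: meals 46.6 ± 27.1 g (low-carb) / 72.5 ± 29.3 g (high-carb),
33% of meals unbolused. Detection is scored by sensitivity, false
discovery rate and detection time with exact Clopper–Pearson intervals;
glycemic outcomes by iAUC (trapezoid above meal-start baseline), time in
range 70–180 mg/dL, time above/below range, and the low blood glucose
index (LBGI ≥ 5.0 flags elevated hypoglycemia risk).

## Worked example

```python
from rap import policy

event = policy.DetectionEvent(
    alert_time=500.0, p_meal=0.91, carb_class=1,          # class 1 = 20-40 g
    estimated_grams=policy.class_to_grams(1),             # 30 g representative
    presumed_meal_time=500.0 - 25.0)
rec = policy.recommend_dose(event, ack_time=500.0, carb_ratio=10.0)
print(rec.units, rec.fraction_applied)
```

prints

```
2.25 0.75
```

— 75% of the nominal 3.0 U meal bolus, because the meal is presumed to
have started 25 minutes before the alert. Waiting 20 more minutes to
acknowledge (`ack_time=520`) drops the recommendation to 1.65 U.

Pipeline from the shell:

```bash
rap simulate --out cohort/ --subjects 10 --days 14 --seed 7
rap featurize --data cohort/ --out features.csv
rap train --features features.csv --out model.rap.npz
rap detect --model model.rap.npz --data cohort/ --out detections.csv
rap evaluate --data cohort/ --detections detections.csv --out report.json
```

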