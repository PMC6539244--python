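# drivestress

Driving-stress classification from wearable electrodermal activity
(EDA) and vehicle speed logs.

Driving stress rises in traffic jams and in city (vs. highway) driving,
and the sympathetic arousal it causes is visible in skin conductance.
This package implements the full analysis chain for studies of that
relationship, for researchers in psychophysiology, biosensing and
transportation human factors: it reads wrist-sensor EDA exports and
OBD-II speed logs, extracts skin conductance response (SCR) features
over sliding windows, builds reference stress labels from traffic
conditions or road type, and fits and evaluates binary logistic stress
classifiers.  A synthetic drive simulator with planted ground truth
makes every stage testable without field data.

## The method

* **Features.**  The conductance signal (µS, nominally 4 Hz) is
  resampled to 15.5 Hz, smoothed with a trailing 60-sample moving
  average, and scanned for SCRs — valley-to-peak excursions with
  amplitude OM (µS) and duration OD (samples).  Over six-minute windows
  sliding by one minute (5580 and 930 samples), each window gets the
  min, max, mean, SD, sum and count of both quantities.
* **Labels.**  *Traffic*: a six-minute speed window with mean speed
  MS < 40 km/h **and** speed SD STDS < 20 km/h (both strict) is a
  traffic jam — high stress; the criterion is selected from a 4 × 5
  threshold grid by classifier agreement, subject to sensitivity and
  PPV ≥ 50%.  *Road type*: city windows are high stress, highway
  windows low stress; boundary- and tollgate-touching windows are
  excluded.
* **Model.**  Binary logistic regression
  p = 1/(1+e^−(β₀+Σβⱼxⱼ)) over ten windowed SCR statistics; high
  stress iff p > 0.5.  Evaluation: accuracy, sensitivity, specificity,
  PPV from the confusion counts; Cox–Snell and Nagelkerke pseudo-R²;
  rank (Mann–Whitney) AUC; stratified drive-grouped 10-fold CV or a
  70/30 split, optionally against five stock comparison learners
  (RF, AdaBoost, naive Bayes, SVM, MLP).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Run both analyses on a simulated month of commuting (25 drives, 4 with
a dead sensor channel, 21 retained):

```python
import drivestress as ds

cfg = ds.RunConfig(seed=1, n_drives=25, n_invalid=4, outdir="results")
res = ds.run_traffic_model(cfg)
print("selected:", tuple(res["selected_thresholds"]))
print("metrics:", {k: round(v, 1) for k, v in res["metrics"].items()})
print("R2:", round(res["r2_cox_snell"], 3), round(res["r2_nagelkerke"], 3))
```

prints

```
selected: (40.0, 20.0)
metrics: {'accuracy': 89.8, 'sensitivity': 94.3, 'specificity': 86.9, 'ppv': 82.3}
R2: 0.561 0.761
```

The grid search recovered the congestion criterion the simulator
planted (mean speed 40 km/h, SD 20 km/h).  The in-sample classification
metrics (percent) and pseudo-R² describe the final fit on the 1155
labeled windows; `res["evaluation"]` holds the honest drive-grouped
cross-validated figures:

```
classifier  sensitivity  specificity   ppv   auc
  Logistic         93.2         86.8  81.9  92.8
```

`res["grid"].table` is the 20-row threshold grid report, and
`results/` receives the grid, model card (coefficient and p-value per
predictor), evaluation table and a JSON run manifest.  The same
configuration drives `ds.run_roadtype_model`, and the `drivestress`
command line exposes `simulate`, `features`, `label-traffic`,
`label-roadtype`, `run-traffic`, `run-roadtype` and `run-all`.

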