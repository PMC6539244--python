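# Methods

## Problem and approach

`drivestress` classifies a driver's stress level (low vs. high) from the
electrodermal activity (EDA) of a wrist-worn sensor, using vehicle speed
and route information to construct the reference labels.  Two parallel
analyses share one feature pipeline:

1. **Traffic-condition model.**  Mean speed (MS) and the sample standard
   deviation of speed (STDS) are computed over consecutive six-minute
   windows of the OBD-II speed log.  A window is *high traffic* — a
   traffic jam, taken as high driver stress — exactly when both fall
   strictly below a criterion pair (MS < m, STDS < s).  The criterion is
   chosen from a 4 × 5 grid (m ∈ {20, 30, 40, 50} km/h,
   s ∈ {10, 15, 20, 25, 30} km/h) by refitting the stress classifier
   under every labeling and maximizing the mean of accuracy,
   sensitivity, specificity and PPV, subject to sensitivity ≥ 50% and
   PPV ≥ 50%.  The retained default is (40, 20).
2. **Road-type model.**  Windows wholly inside a city segment are high
   stress, wholly inside a highway segment low stress; windows that
   straddle a boundary or touch a tollgate mix both conditions and are
   excluded.

Both models are binary logistic regressions
p_i = 1/(1 + exp(−(β₀ + Σ β_j x_ij))) over windowed skin-conductance
response (SCR) statistics, with the 0.5 rule (high stress iff p > 0.5,
ties low).

## Signal chain

* **Input**: conductance in µS at a nominal 4 Hz.
* **Resampling**: linear interpolation onto a 15.5 Hz grid.  At that
  rate a six-minute window is exactly 5580 samples and a one-minute
  slide 930 samples, so window bookkeeping stays in whole samples.
  Linear interpolation is the simplest method consistent with an
  upsample and with downstream peak finding.
* **Smoothing**: trailing (causal) 60-sample moving average with prefix
  shortening.  Causal alignment suits streamed physiological data; the
  prefix rule keeps the output the same length as the input.
  Smoothing is applied after resampling; both steps are configurable.
* **SCR events**: peaks and valleys are local extrema with topographic
  prominence ≥ 0.01 µS (the sensor's resolution floor; configurable),
  alternation-enforced (of consecutive same-type extrema the more
  extreme survives).  Each peak is paired with its nearest preceding
  valley; the event's amplitude `om` is the conductance rise (µS) and
  its duration `od` the rise time in samples.  Peaks with no preceding
  valley or a non-positive rise are dropped.
* **Features**: per window, min / max / mean / SD / sum / count of both
  `om` and `od` (12 statistics).  An event belongs to the window
  containing its peak.  SDs use the n−1 formula and are 0 for
  single-event windows.  Event-free windows keep zero features plus an
  `empty` flag (droppable via config) so the matrix stays rectangular.
  The duration and amplitude counts are equal by construction, so the
  default model feature set is ten predictors: the count `n`, five
  amplitude statistics, and four duration statistics (the duration SD
  is withheld as nearly redundant with the other duration statistics;
  the set is configurable).

Six-minute *traffic* windows tile without overlap while *feature*
windows slide by one minute; a feature window inherits the label of the
traffic window containing its midpoint — the least ambiguous join.

## Model fitting and evaluation

Logistic models are fitted by maximum likelihood (Newton iterations,
log-likelihood tolerance 1e-8, at most 100 iterations; BFGS fallback on
a singular Hessian).  Perfect separation — the signature being a fitted
linear predictor beyond ±30, where the likelihood is flat to machine
precision — triggers a warning and the coefficients are scaled down so
predictions stay finite; reported log-likelihoods are those of the
unconstrained fit.  Wald p-values are reported per coefficient and
never used for selection.

Evaluation uses the confusion counts with high stress positive:
A = (TP+TN)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP);
a zero denominator marks that metric undefined rather than zero.
Goodness of fit: Cox–Snell R² = 1 − exp(2(ll₀ − ll₁)/n) and its
Nagelkerke rescaling to a unit maximum.  Ranking: rank-based
(Mann–Whitney) AUC with midranks for ties.

The comparison harness runs any fit/predict classifiers — by default
the package's logistic model, optionally random forest, AdaBoost,
naive Bayes, SVM and MLP at library defaults — under stratified 10-fold
cross-validation (pooled out-of-fold predictions) or one stratified
70/30 split.

**Grouped folds.**  Sliding windows overlap five-sixths with their
neighbours, so windows from one drive are strongly dependent and share
their label over long runs.  With ordinary stratified folds a
classifier can recognize held-out windows of a drive segment it partly
saw during training, which inflates apparent performance (measured
no-signal AUC of 62–78% on synthetic nulls).  The pipeline therefore
keeps whole drives together in folds (stratified group K-fold; group
shuffle for the 70/30 split).  Plain stratified folds remain available
when no groups are passed.

## Synthetic drives

No field recordings ship with the package; the generator produces
drives with known ground truth so every stage is testable.

* **Route**: ~60 min, five main segments — City 1 (600 s), three
  highway stretches (720 s each) separated by two 60 s tollgates, City 2
  (720 s) — matching a commuter route with ~22 min of city and ~36 min
  of highway driving.
* **Speed** (1 Hz): Gaussian per segment kind, floored at 0 —
  city 35 ± 15 km/h (stop-and-go), highway 90 ± 12, tollgate 30 ± 10.
  Planted congestion episodes (six-minute, window-aligned, mean
  20–30 km/h, SD 5–12 km/h — strictly inside the (40, 20) criterion)
  override the segment regime.
* **Latent stress**: high during city driving and congestion, low
  otherwise.
* **EDA** (4 Hz): tonic level 0.3 µS plus a slow sinusoidal drift
  (0.05 µS, 20 min period, random phase — sweat-level drift is not
  synchronized to the route) plus SCR kernels at Poisson times (at most
  one onset per second) plus 0.003 µS white noise, floored at 0.  Event
  rate 4/min in the low state and 12/min in the high state; amplitudes
  log-normal with medians 0.05 and 0.15 µS (log-SD 0.4); kernels rise
  linearly over 1–3 s and decay exponentially (τ = 4 s).  The event
  process gets 120 s of burn-in and run-out so the signal is stationary
  from its first sample — without it the route's first windows (always
  City 1) are systematically event-poor, a label leak.
* **Batches**: day-indexed drives from one seed via named substreams
  (component-wise reproducible).  A configurable number of drives get a
  dead (all-zero) conductance channel, emulating sensor failures; the
  validity filter drops them (default batch: 25 drives, 4 spoiled,
  21 retained).

What the generator does **not** emulate: physiologically calibrated
sudomotor dynamics, motion artifacts, electrode drift/detachment,
temperature and humidity effects, heart-rate channels, and real traffic
dynamics (it draws i.i.d. speeds per regime rather than car-following
behavior).  Passing tests therefore demonstrate that the pipeline
recovers the structure this generator plants — not field performance.

## Problem sizes and calibration checks

The planted-truth checks run on a 21-drive batch (the size of a
month-long weekday campaign): the grid search must recover (40, 20) and
grouped-CV AUC must exceed 0.8 for both models.  The no-signal
calibration (identical SCR statistics in both states) instead uses
60 drives and *tiled* (non-overlapping) windows: chance-level AUC is a
sharp statement, and overlapping windows leave so few independent cases
that a 21-drive null estimate swings by ±10 points; tiling and the
larger batch bring the spread inside a few points of 50%.

## Numerical choices and edge cases

* Time intervals are half-open [start, end) everywhere; a sample
  belongs to the segment containing its timestamp.  A timestamped speed
  log covers one median sampling interval past its last timestamp.
* Threshold comparisons are strict ("lower than"); a window at exactly
  MS = 40 km/h is low traffic.  Grid selection ties keep the first pair
  in grid order (mean-speed-major).
* A grid row whose labeling leaves fewer cases in either class than the
  model has parameters (+2) is flagged degenerate: an in-sample fit
  memorizes a handful of windows and would report perfect, meaningless
  metrics.  If no pair clears the sensitivity/PPV floor the default
  criterion (40, 20) is kept, with a warning.
* p = 0.5 classifies as low stress (strictly-greater rule).
* Cox–Snell R² is computed with `expm1`; it still saturates to 1.0 when
  the likelihood ratio falls below double resolution.
* Resampling clamps the few output instants past the last source sample
  to its value and always emits at least one sample.
* Flat or monotone signals yield no extrema (not an error); signals
  shorter than one window yield an empty feature table with a warning.

## Known limitations

* The traffic grid search scores candidate labelings in-sample, as a
  model-development report; only the grouped CV/split figures are
  out-of-sample estimates.
* The road-type and traffic labels are both driven by the same latent
  state in the generator, so the two analyses are not independent
  evidence about a synthetic batch.
* With strongly separated synthetic classes the logistic fit routinely
  hits quasi-separation; capped coefficients keep predictions stable
  but their printed magnitudes are then not maximum-likelihood
  estimates.
* The five comparison learners are stock implementations at library
  defaults; no tuning is attempted.
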