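# Methods

`vapwarn` implements an end-to-end study of early ventilator-associated
pneumonia (VAP) prediction from five routinely monitored vital signs:
respiratory rate, heart rate, mean arterial pressure, body temperature and
SpO2. This note records the models, rules and numerical choices the package
makes, and what its synthetic benchmark does and does not demonstrate.

## Study design

A patient on invasive mechanical ventilation (MV) for more than 48 h enters
a *risk period* running from 48 h after MV initiation to 72 h after the end
of the episode; pneumonia with onset in this interval is attributed to the
ventilator. The classifier consumes 24 h observation windows of hourly
vital signs and outputs the probability that a VAP onset occurs within a
prediction horizon of 6, 12 or 24 h after the window ends. One model is
trained per horizon because the labels differ per horizon.

## Episode construction

Raw ventilation segments of one patient are merged when the gap between
them is strictly less than 24 h (temporary weaning, procedural pauses);
overlapping segments always merge. Episodes lasting 48 h or less are
discarded (strict inequality: exactly 48 h is excluded, matching "more
than 48 h"). Timestamps are integer minutes throughout, so rule
boundaries are exact comparisons with no float-equality hazards. Gaps of
24–48 h are treated as episode boundaries; the status of such gaps under
non-invasive ventilation is genuinely ambiguous in the underlying
definitions, and the boundary choice is recorded here.

## VAP annotation

An episode acquires a VAP event when

1. a positive respiratory culture (bronchial aspirate, BAL or tracheal
   aspirate) is collected inside the risk period, and
2. a *new* antibiotic regimen targeting respiratory pathogens starts
   within 72 h before to 24 h after the culture (both limits inclusive).

The onset is the earlier of the culture and antibiotic times. Candidate
events with onsets less than 48 h apart are chained (single linkage) into
one infection event keeping the earliest onset. "New" is an input flag:
real-data adapters must derive continuation-vs-new upstream; the simulator
sets it directly.

The onset, being the minimum of the two times, can in principle precede
the risk period when an antibiotic starts well before a culture collected
just inside it; the rules do not clamp it. The synthetic generator places
both times inside the risk period, so on generated cohorts every onset
lies within it.

Control episodes are selected 1:1 by greedy nearest-neighbour matching
without replacement in seeded random order: exact match on sex, distance =
sum of absolute standardized differences in age, SAPS-II and log MV
duration, caliper 2.0 standardized units (configurable). Greedy matching
is used rather than optimal assignment because it is simple, standard and
reproducible; no caliper or algorithm is prescribed by the study design.

## Windowing and labelling

Vitals are gridded hourly (cell = mean of observations in that hour),
interior gaps filled by linear interpolation, leading/trailing gaps by
nearest-value extension; an episode missing a variable entirely, or with
fewer than two observed hours of one, is excluded. Windows slide at 1 h
stride; a window is emitted when its end lies in the half-open risk
period. The label for horizon h is 1 iff an onset lies in
`(obs_end, obs_end + h]` — an onset 4 h past the window end is positive at
the 6 h horizon.

**Censoring.** Windows whose observation interval reaches an onset or
overlaps the 48 h of active infection after it (`obs_end >= onset` and
`obs_start < onset + 48 h`) are suppressed. A window that already observes
the infection is neither a valid negative nor a prediction task; leaving
such windows in as "negatives" would make the label adversarial exactly
where the signal is strongest. This is an explicit design choice of this
package, not a rule taken from any cohort study.

## Splitting

Units are episodes (window-level splitting exists behind a flag but leaks
temporally overlapping information between splits and is for fidelity
experiments only). Episodes are stratified on whether they contain any
positive window and randomized into 60/20/20 train/validation/test.
Integer rounding of a handful of positive episodes per split makes a naive
draw routinely violate a 20 %-relative balance band, so the split uses
rerandomization: up to 50 deterministic redraws, accepting the first
assignment whose per-split positive-window fractions are all within 20 %
relative of the global fraction (else the best found). Cross-validation
folds are built by greedy balanced assignment of groups to folds (positive
mass first, then size), which keeps fold prevalences tight at small n.

## Class rebalancing

SMOTE runs after splitting, on the training portion only, in the flattened
120-dimensional window space: a synthetic positive is `x + λ(z − x)` with
`x` a minority window, `z` one of its k = 5 nearest minority neighbours
(Euclidean) and `λ ~ U(0,1)`, generated until positives equal negatives
(target ratio 1.0). Because consecutive windows of one episode overlap by
23 h, nearest minority neighbours are mostly phase-adjacent windows of the
same event, so synthetics resemble slightly phase-blurred positives. This
blurring measurably softens the decision boundary of flexible models; it
is retained because rebalancing by SMOTE at full balance is part of the
study pipeline being implemented.

## Model

A stacked LSTM: 3 layers of 50 cells, dropout 0.10 between layers
(search set {0.05, 0.10}), a fully connected sigmoid read-out on the final
hidden state; gate order (input, forget, cell, output), forget-gate bias
initialized to 1, orthogonal recurrent initialization. The implementation
is NumPy throughout — forward, backpropagation through time, inverted
dropout and Adam — in float32, fully deterministic under a fixed seed, and
exposes exact input gradients for attribution.

Z-scored inputs are multiplied by a fixed `input_scale = 1/3` before the
first layer. Pre-onset excursions reach several standard deviations in
normalized units; unscaled, they sit in the saturated tails of the gate
nonlinearities, and training plateaus early. The scale is a conditioning
constant, not a tuned hyperparameter, and is exposed in `ModelConfig`.

Training minimizes binary cross-entropy with Adam (default learning rate
1e-3, batch 64; the scaled study runs use batch 256), with an L2 penalty
of 3e-3 on weight matrices (not biases): the SMOTE-balanced training set
is nearly separable, so unpenalized training fits it within an epoch or
two and stops refining the ranking. Early stopping monitors validation
AUPRC with configurable patience and the best-epoch parameters are
restored. Epoch count, batch size and patience are not prescribed by the
study design and are exposed with defaults (100/64/10). Hyperparameter
search is a grid over cells, dropout and learning rate scored by
validation AUPRC, ties broken toward fewer parameters then lower dropout.
The relationship between the 60/20/20 split and 5-fold cross-validation is
implemented as: CV and hyperparameter search operate on the training
portion; the final model is refit on train, thresholded on validation and
reported on test.

The decision threshold is the score at which precision equals recall
(sensitivity = PPV): an exhaustive scan over unique scores minimizing
|precision − recall|, ties toward higher recall, then the lower threshold.

## Comparators

Random forest, gradient-boosted trees (XGBoost) and logistic regression
consume the identical SMOTE-balanced training matrix with windows
flattened row-major by hour (feature 0 = hour-0 respiratory rate, feature
119 = hour-23 SpO2; the flattening is a bijection). Hyperparameters are
library defaults apart from 500 trees for the ensembles and fixed seeds.

A caveat on interpreting the comparison on *synthetic* cohorts: the
planted signature is a smooth monotone drift plus a variance rise, and the
decision boundary induced by any horizon threshold is close to linear in
per-cell level and slope functionals. A linear model over the 120 cells
is therefore near-optimal on this benchmark and is not expected to
reproduce the degradation that non-sequential models show on real ICU
data, where the predictive structure is not a clean parametric ramp. On
this benchmark logistic regression matches or slightly exceeds the
sequence model at the 24 h horizon; the benchmark demonstrates signal
recovery, leakage-free plumbing and calibrated uncertainty, not an
architectural ranking.

## Evaluation

AUPRC is average precision (step-wise summation; trapezoids over PR space
are biased), AUROC trapezoidal with tied scores grouped. `score >=
threshold` is positive. Confusion-derived metrics report NaN, never 0, for
undefined ratios. Confidence intervals are percentile bootstrap over
resampled (score, label) pairs, n = 100, degenerate single-class resamples
skipped and logged; windows (not patients) are resampled, with a
patient-level option considered experimental. Model comparison is a paired
bootstrap on AUPRC (same resample indices for both models), two-sided
p-value `2·min(P(Δ≤0), P(Δ≥0))` floored at 1/(n+1). Calibration uses 10
equal-width bins over [0,1] (empty bins omitted) plus the Brier score.

## Explainability

Integrated gradients with a midpoint Riemann sum (default 50 steps; the
completeness gap — |Σ attributions − (f(x) − f(baseline))| — is reported
per window and shrinks as steps grow). The baseline is all-zeros in
normalized space, i.e. the per-variable training mean in raw units:
attributions measure the effect of deviating from an average patient-hour,
and all attribution values depend on this choice. Per-variable importance
aggregates mean |attribution| over windows and timesteps (a signed-mean
rule is available); the rule identifier is recorded in every output.

## Synthetic cohort: generative model

No public vital-sign generator reproduces the study conditions, so the
package ships its own. Per patient: one eligible MV episode (duration
lognormal, median 84 h, log-sd 0.25, clipped to 60–200 h), occasionally
split by an interior <24 h gap (exercises merging) or accompanied by a
short decoy segment (exercises the duration filter). Each vital follows

    value(t) = baseline + patient offset + circadian sinusoid
               + signature(t)·drift + AR(1) deviation + instability(t)·ε

with conventional adult ICU baselines (RR 18 /min, HR 80 /min, MAP
85 mmHg, T 37.0 °C, SpO2 97 %), patient-level offset sds (1, 3, 3, 0.1,
0.5 in the same order), circadian amplitudes (0.5, 2, 2, 0.15, 0.3),
mean-reverting noise sds (1.2, 3.0, 3.5, 0.15, 0.6) with lag-1 h
autocorrelation 0.4, and charting times jittered around a 15 min median
interval. SpO2 is clipped to (50, 100]; values are rounded to 0.1.

VAP-positive episodes (prevalence: configurable fraction of episodes)
receive, over a pre-onset ramp of 48 h (per-event duration jitter ±15 %,
per-event amplitude jitter ±7 %):

* a **convex quadratic drift** reaching +6 breaths/min RR, +15 beats/min
  HR, −5 mmHg MAP, +1.2 °C T, −4 % SpO2 at onset (amplitude 1) —
  accelerating deterioration, the clinically plausible shape of an
  incubating pneumonia;
* a **heteroscedastic instability** term: extra white noise whose sd rises
  linearly over the same window to 2× the base sd at onset. Prodromal
  variability precedes the overt mean drift; it carries second-moment
  information that a linear model cannot read from the raw cells directly
  (though a muted linear shadow of it survives, e.g. through the SpO2
  ceiling at 100 %, where higher variance truncates to a lower mean).

After onset the signature decays linearly over 24 h (treatment effect).
Onsets are placed uniformly inside the risk period (2 h margins keep rule
boundaries unambiguous); the matching culture/antibiotic pair is emitted
with the earlier time at the onset. Distractors per episode (Poisson, rate
configurable): positive respiratory cultures placed so no qualifying
antibiotic falls in their window, qualifying antibiotics placed clear of
any positive culture's window, plus events failing the specimen or
new/respiratory flags. Missingness drops an exact fraction of records
uniformly, refusing any drop that would open a ≥24 h gap in a stream.

The signal-to-noise calibration above was chosen once so that the injected
signature is recoverable at the package's stated operating point (test
AUPRC ≥ 0.90 at the 6 h horizon on a ~330-episode matched cohort) and then
frozen; it is a property of the benchmark, not a fit to any external data.

**What the generator does not emulate:** real VAP heterogeneity (organism,
host response), ventilator settings and mode changes, treatment
confounding beyond a one-shot decay, informative missingness, charting
artifacts, inter-variable noise correlation, and MIMIC-IV's actual
vital-sign distributions (no public calibration target exists). Passing
the synthetic benchmark shows the pipeline recovers a planted, plausible
signal under irregular sampling, missingness, distractor events and class
imbalance — it says nothing about clinical performance.

## Problem sizes

Unit and property tests run on toy data. The study-scale checks use a
550-patient cohort (≈330 matched episodes, ≈29 000 windows) for signal
recovery and model comparison, a 300-patient signal-free cohort for the
degradation-to-chance check, a 200-patient cohort for annotation recovery,
and a 60-patient cohort with a reduced model for the end-to-end
determinism check; LSTM training at study scale uses batch 256 and ≤20
epochs with patience 6. These sizes are the package's choices for a
reproducible desk-scale benchmark.

## Known limitations

* The annotation "new antibiotic" flag is trusted input, not derived from
  prescription history.
* The LSTM is trained on SMOTE-balanced data as the pipeline prescribes;
  class-weighted training without SMOTE is measurably better for the
  sequence model on this benchmark but is not the implemented design.
* Bootstrap CIs resample windows, ignoring within-episode correlation;
  they are narrower than patient-level resampling would give.
* Percentile bootstrap at n = 100 is approximate; its coverage is checked
  only within a broad band.
* With a single eligible episode per simulated patient, episode-level and
  patient-level grouping coincide in the benchmark.
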