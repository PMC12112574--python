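# vapwarn

Early prediction of ventilator-associated pneumonia (VAP) from five
routinely monitored vital signs — respiratory rate, heart rate, mean
arterial pressure, temperature and SpO2.

VAP strikes a sizeable fraction of ICU patients on invasive mechanical
ventilation (MV) and its diagnosis is retrospective: clinical suspicion,
then a respiratory culture, then antibiotics. `vapwarn` implements, end to
end and fully reproducibly, a study pipeline that asks whether the vital
signs alone, as displayed on any ICU monitor, carry enough signal to
predict VAP onset 6, 12 or 24 hours ahead:

* **Synthetic cohorts** in a MIMIC-like event schema (demographics,
  ventilation segments, irregular vital-sign streams, microbiology,
  antibiotic starts) with injected pre-onset physiological signatures,
  distractor events, irregular sampling and missingness — every downstream
  stage is testable without any credentialed data access.
* **MV episodes**: ventilation segments merged across interruptions < 24 h;
  episodes > 48 h are eligible; the VAP **risk period** runs from 48 h
  after MV start to 72 h post-extubation.
* **Rule-based VAP annotation**: a positive respiratory culture inside the
  risk period linked to a new respiratory antibiotic starting within
  [−72 h, +24 h] of the sample; onset = the earlier of the two; events
  < 48 h apart merge. 1:1 matched control selection (exact sex, nearest
  neighbour on age, SAPS-II, log MV duration).
* **Windowing**: hourly resampling, linear interpolation, z-scoring with
  training statistics, 24 h windows sliding at 1 h; the label for horizon
  h is whether an onset falls in `(obs_end, obs_end + h]`; SMOTE
  rebalancing of the training split; stratified episode-level 60/20/20.
* **Models**: a 3-layer, 50-cell LSTM implemented in NumPy (forward, BPTT,
  Adam, dropout — no deep-learning framework required), against random
  forest, XGBoost and logistic regression on the identical flattened data.
* **Evaluation**: AUPRC (average precision) and AUROC, sensitivity /
  specificity / PPV / NPV / Youden at the precision = recall threshold,
  95 % percentile-bootstrap CIs (n = 100), paired bootstrap model
  comparison, calibration curves and the Brier score.
* **Explainability**: integrated gradients over the 24×5 input with
  completeness-gap reporting and per-variable importance.

See `docs/methods.md` for the full model and every numerical convention.

## Worked example

```python
from vapwarn import CohortConfig, simulate_cohort
from vapwarn.model import ModelConfig
from vapwarn.pipeline import PipelineConfig, run_pipeline

tables = simulate_cohort(CohortConfig(n_patients=550, vap_prevalence=0.3, seed=42))
report = run_pipeline(
    tables,
    PipelineConfig(
        horizons=(6, 24),
        baselines=("logistic_regression",),
        model=ModelConfig(max_epochs=16, patience=6, batch_size=256, seed=7),
        seed=7,
    ),
)
for h, entry in report["horizons"].items():
    models = entry["evaluation"]["models"]
    print(h, {name: round(m["auprc"]["point"], 3) for name, m in models.items()})
```

prints (one model per horizon; exact values for these seeds)

```
6 {'lstm': 0.903, 'logistic_regression': 0.949}
24 {'lstm': 0.971, 'logistic_regression': 0.977}
```

Read: on a ~330-episode synthetic matched cohort the sequence model
recovers the planted pre-onset signature well at both horizons (test AUPRC
0.90 at 6 h, 0.97 at 24 h against window prevalences of a few percent). At
the precision = recall operating point the 6 h model reaches sensitivity
0.86 and PPV 0.80 with a Brier score of 0.016. Note that the flattened
logistic-regression comparator is *not* weak on this benchmark: the
injected signature is a smooth monotone drift, which is exactly what a
linear read-out of the 120 window cells detects efficiently — see
`docs/methods.md` for why this differs from real cohorts. The report also
carries per-metric bootstrap CIs, the confusion matrix at the selected
threshold, Brier/calibration summaries, and integrated-gradients feature
importances; `report["annotation_audit"]` confirms the rule-based
annotator recovered all 166 planted events with zero false positives.

The same stages are scriptable from a shell:

```bash
vapwarn simulate --config cohort.yaml --out cohort/ --seed 42
vapwarn annotate --cohort cohort/ --out annotated/
vapwarn run --cohort cohort/ --horizons 6,24 --baselines logistic_regression --out results/
```

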