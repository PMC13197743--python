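# oxiscreen

Multidimensional nocturnal pulse-oximetry analysis for obstructive sleep
apnea (OSA) screening. The package covers the full workflow:

1. **Signal ingestion** (`oxiscreen.spo2_io`) — delimited-text or EDF SpO2
   recordings at any native rate, reduced to a canonical 1 Hz masked signal,
   with a >4 h analyzable-duration validity rule.
2. **Synthetic cohorts** (`oxiscreen.synthetic_cohort`) — seeded 1 Hz signals
   with configurable desaturation rate/depth/duration, noise, and labeled
   OSA / non-OSA cohorts (label rule: ≥ 5 qualifying events/h), each with a
   ground-truth generation log.
3. **Desaturation events** (`oxiscreen.desat_events`) — nadir detection,
   rainwater-trapping window delineation (75% amplitude recovery, mean-
   duration cap, 100 s pre-window baseline), ODI (≥ 4% drops per hour of
   sleep) and hypoxic burden (baseline-deficit area, %·min/h).
4. **Summary features** (`oxiscreen.oximetry_summary`) — MeanSpO2, MinSpO2,
   T90/ST90, attention entropy over extrema-interval streams, and
   Lomb–Scargle ultradian-band (0.014–0.035 Hz) spectral power; assembly of
   the canonical 8-parameter vector.
5. **Model development** (`oxiscreen.model_dev`) — z-scoring and SMOTE
   confined to training folds, stratified 5-fold CV over six classifier
   families, exhaustive 1–4-parameter subset search ranked by F1 (ties: AUC,
   then names), retraining without oversampling, external validation, and
   the seven-metric evaluation suite with rank-based AUC.
6. **Interpretation** (`oxiscreen.interpret`) — restricted-cubic-spline
   logistic nonlinearity tests (df = 5 spline vs linear, 4-df LRT), exact
   Shapley attributions with normalized importances, and sex/age subgroup
   re-runs.
7. **Pipeline CLI** (`oxiscreen.cli_pipeline`) — reproducible end-to-end runs
   with manifests.

## CLI

```bash
# synthesize a labeled cohort of 1 Hz signals
oxiscreen generate --out runs/cohort --n 100 --prevalence 0.55 --seed 7

# extract the 8 oximetry features (4 h validity rule by default)
oxiscreen extract --signals runs/cohort/signals \
                  --metadata runs/cohort/cohort.csv --out runs/features

# subset search + selection + retraining + RCS/SHAP/subgroup reports
oxiscreen develop --features runs/features/features.csv \
                  --out runs/develop --seed 7

# score an external cohort with the saved model
oxiscreen validate --model runs/develop/best_model.pkl \
                   --features runs/features/features.csv --out runs/external
```

`develop` accepts a YAML config (`--config`) with keys `sizes`, `families`,
`n_folds`, `seed`, `threshold`, `smote_k`, `scale_in_fold`, `run_rcs`,
`run_shap`, `run_subgroups`, `subgroup_sizes`, `subgroup_families`, `rcs_df`.
All outputs are delimited text plus a JSON manifest; runs are byte-
reproducible under a fixed seed.

## Notes

- The six classifier families are configured from the published
  hyperparameter table and backed by scikit-learn estimators (the three
  gradient-boosting variants map onto `HistGradientBoostingClassifier`
  configurations; unmappable engine-specific keys are recorded in the run
  manifest).
- SMOTE and Shapley attribution are implemented in-package; with ≤ 8
  features the Shapley values are computed by exhaustive coalition
  enumeration and are exact for every model family.
- Absolute spectral-power dB levels and attention-entropy scale are
  implementation-defined; analyses relying on them use relative quantities
  (in-band fractions, normalized importances).
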