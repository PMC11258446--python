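# metaboage

Multi-cohort NMR-style metabolomic aging models: preprocessing and
between-cohort calibration, metabolome-wide association studies (MWAS)
pooled by fixed-effect meta-analysis, four trainable age/lifespan models,
cross-validated evaluation, and chronological-age-adjusted association
analyses — exercised end to end on a built-in synthetic multi-cohort
generator (no external data required).

## What is in the box

| Module | Purpose |
| --- | --- |
| `metaboage.synthetic` | Multi-cohort metabolite + phenotype simulator: per-cohort age windows (24–86 y overall), latent-factor metabolite correlation, linear and hinge-shaped age trends, mortality-driving analytes (some opposing their age trend), multiplicative batch effects, cohort-level missing analytes, multivariate outliers, repeat visits. |
| `metaboage.preprocess` | Variable QC (missingness, replicate correlation r < 0.7), robust-PCA outlier weights (weight ≤ 0.1 ⇒ removed), demographically matched between-cohort calibration, k-NN imputation, VIF ≥ 5 backward pruning. |
| `metaboage.mwas` | Per-cohort MWAS of age (linear, sex/BMI/ethnicity-adjusted) and mortality (Cox, CA/sex/BMI-adjusted), age-group-stratified MWAS, inverse-variance fixed-effect meta-analysis with Cochran's Q / I², Benjamini–Hochberg FDR. |
| `metaboage.mars` | Self-contained degree-2 multivariate adaptive regression splines: reflected hinge-pair forward search, GCV backward pruning, variable importance, JSON serialization. |
| `metaboage.enet` | Elastic net (coordinate descent) with per-variable penalty multipliers and CV lambda selection. |
| `metaboage.models` | The four aging models — elastic net on CA, MARS on CA, phenotypic age (mortality-p-value penalty factors with the opposing-direction rule), penalized-Cox mortality score rescaled to age units — plus published-score coefficient tables (log transform, per-cohort z-scaling, k-NN imputation of missing analytes). |
| `metaboage.evaluation` | 7-fold cross-validation with subject-level folds, leave-one-cohort-out validation, longitudinal δ-age concordance. |
| `metaboage.associations` | CA-adjusted linear associations with binary risk factors and SD-scaled biomarkers, CA-adjusted Cox models for incident events (HR per year of metabolomic age), BMI sensitivity adjustment, p < 0.001 reporting rule. |
| `metaboage.pipeline` / `metaboage.cli` | Config-driven end-to-end runs with per-stage outputs and a SHA-256 manifest; a single seed drives every stochastic choice. |

## CLI

```sh
metaboage run --seed 17 --out out/            # full pipeline, default scale
metaboage simulate --config sim.yaml --seed 17 --out data/
metaboage preprocess --in data/ --reference C03 --vif-threshold 5 --out prep/
metaboage mwas --in prep/ --outcome mortality --out res/
metaboage fit --in prep/ --model mars --out models/
metaboage score --in prep/ --table deelen_style.csv --out scores/
metaboage evaluate --in prep/ --model models/model_mars.json --scheme loco --out eval/
metaboage associate --in prep/ --model models/model_mars.json --out assoc/
```

All tabular artifacts are CSV (`NA` missing token, strict schema checks);
models and reports are JSON. Re-running with the same config and seed is
byte-identical.

## Notes and caveats

- The outlier weighting is a contract-compatible substitute for the
  reference robust-PCA scheme (median/MAD standardization, PCA at 99%
  variance, chi-square-gated weights), not a replica.
- Calibration factors default to multiplicative median ratios on
  sex × 5-year-age × BMI-class × ethnicity matched strata; mean/additive
  variants are configurable.
- Within-subject metabolite dynamics use a subject random intercept plus
  shared latent-factor scores — a stand-in, since real within-subject
  autocorrelation is not characterized.
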