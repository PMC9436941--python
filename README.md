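# egfr-selector

Per-patient selection of glomerular filtration rate (GFR) estimation
equations with a classification decision tree.

Instead of applying one eGFR equation to every chronic-kidney-disease
patient, this package labels each patient with the candidate equation whose
estimate best matches their measured GFR, trains an entropy/information-gain
decision tree to predict that label from clinical covariates, and then
estimates GFR by dispatching each patient to the predicted equation.

## What is included

| module | contents |
| --- | --- |
| `egfr_selector.equations` | 13 eGFR equations (Cockcroft-Gault, MDRD family, CKD-EPI family, BIS-2, MacIsaac, Ruijin, Xiangya), creatinine unit conversion (88.4 umol/L per mg/dL), Du Bois body surface area, 1.73 m&sup2; normalization, `PatientRecord` |
| `egfr_selector.cart` | from-scratch CART-style classification tree: entropy/gini impurity, information-gain splits over mixed numeric/categorical covariates, variable importance, JSON serialization |
| `egfr_selector.pipeline` | best-match labeling among the 4 candidate equations (BIS-2, CKD-EPI(CysC), CKD-EPI(Cr-CysC), Ruijin), seeded 70/30 splitting, selector training, dispatch estimation, end-to-end `run_pipeline` |
| `egfr_selector.evaluation` | RMSE, MAE, Bland-Altman agreement (bias +/- 1.96 SD), per-method comparison report (13 equations + selector), optional plots |
| `egfr_selector.synthetic` | synthetic cohort generator with configurable marginals and a planted equation-selection structure; analytic inverses of the monotone equations |
| `egfr_selector.cohort` | cohort CSV contract and record/frame conversion |

## CLI

```bash
# generate a synthetic cohort (optionally with the planted labels sidecar)
egfr simulate --n 518 --seed 7 --out cohort.csv --with-hidden-labels

# all 13 equations for every patient
egfr compute --in cohort.csv --out egfr.csv

# stage-wise: label -> train -> predict
egfr label   --in cohort.csv --out labeled.csv --seed 7
egfr train   --in labeled.csv --params params.yaml --out tree.json
egfr predict --in cohort.csv --tree tree.json --out predictions.csv

# or everything from a config
egfr run --config config.yaml
```

Example `config.yaml`:

```yaml
seed: 7
synthetic: {n: 518}        # or: input: cohort.csv
train_fraction: 0.7
tree: {max_depth: 5, min_samples_split: 20, min_samples_leaf: 7}
eval_subset: test
outdir: out/
```

`egfr run` writes `labeled_cohort.csv`, `tree.json`, `importance.csv`,
`metrics.csv` (method, rmse, mae, bias, loa_low, loa_high, mean, p25, p75,
n), `bland_altman.csv` and `run_summary.json`.

## Cohort CSV contract

One row per patient. Core columns: `patient_id, age, sex, height, weight,
scr, scr_unit, cysc, bun, alb, sgfr_abs` with `sex` coded `male`/`female`,
`scr_unit` in {`mg/dL`, `umol/L`} (default `umol/L`), `cysc` mg/L, `bun`
mmol/L, `alb` g/L, `sgfr_abs` mL/min. Clinical covariates follow as 0/1
flags (`diabetic_nephropathy`, `rasi`, ...), categories
(`hypertension_grade`, `renal_pathology`) and numeric measurements
(`urine_protein_24h` mg, `urine_volume_24h` L). Missing values are empty
cells. See `egfr_selector.cohort.COHORT_COLUMNS`.

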