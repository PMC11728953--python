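# rdpredict

Predicting **rapid decline (RD) of kidney function** in type-2 diabetes from
longitudinal laboratory data.

A subset of diabetes patients experiences a sudden, steep loss of kidney
function — estimated glomerular filtration rate (eGFR) falling faster than
5 mL/min/1.73 m² per year — that is not always preceded by the classic
albuminuria signal. `rdpredict` implements a complete, tested analysis
pipeline for flagging these patients a year in advance from the laboratory
tests already collected in routine diabetes care. It is aimed at clinical
data scientists and epidemiologists working with EHR-style long-format lab
tables; because real hospital data cannot be redistributed, the package
ships a synthetic-EHR generator with known ground truth so every stage is
runnable and testable out of the box.

## What it does

1. **RD labeling** — each patient's eGFR trajectory is LOWESS-smoothed
   (tricube local linear regression, robustifying iterations) and every
   eGFR test date *t* is classified:

   RD  ⇔  ŝ(t) < 60 mL/min/1.73 m²  and  ŝ(t − 365 d) − ŝ(t) ≥ 5 mL/min/1.73 m²

   where ŝ is the smoothed curve and ŝ(t − 365 d) is read off by linear
   interpolation. Dates with less than a year of history cannot be RD.
2. **Decision points** — eligible prediction instants: eGFR test dates
   before the patient's first RD indication, not censored by prior dialysis
   or transplant, with at least one further eGFR test in the following
   year. The label is whether an RD indication occurs within that year.
3. **Space features** — per lab test, observations in the 54-week (378-day)
   input window are nearest-neighbour interpolated to daily values (no
   extrapolation), partitioned into 27 two-week *spaces*, and each space is
   represented by ln(mean daily value). Columns are named
   `1st_space_of_<test>` … `27th_space_of_<test>`; missing stays missing.
4. **Model** — a leaf-wise gradient-boosted tree ensemble (LightGBM) with
   cross-entropy loss, native missing-value routing, early stopping on
   validation PR-AUC, and recursive feature elimination: 5 % of the
   starting feature count removed per step (by gain importance) while more
   than 40 remain, then one at a time, with patient-grouped cross-validated
   metrics at every size.
5. **Evaluation** — patient-level 70/30 holdout, six metrics (ROC-AUC,
   PR-AUC, accuracy, recall, precision, F1) with 95 % percentile bootstrap
   CIs (1000 resamples), VIF multicollinearity diagnostics, and an
   RD-vs-not_RD characteristics table (Mann-Whitney U, Fisher exact with a
   Freeman–Halton extension for multi-bin categories).

## Worked example

```python
import numpy as np
import pandas as pd
import rdpredict as rp

config = rp.GeneratorConfig(n_patients=200, seed=42)
patients, labs, truth = rp.generate_cohort(config)

indications = rp.label_cohort(labs, rp.RdCriteria())
windows = rp.StudyWindows(
    decision_end=pd.Timestamp(config.study_end) - pd.Timedelta(days=365))
decision_points, counts = rp.extract_decision_points(patients, indications, windows)
X, y = rp.build_feature_matrix(decision_points, labs, sorted(labs["test_code"].unique()))
print(counts, X.shape)
```

prints

```
{'candidates': 2179, 'excluded_censored': 0, 'excluded_post_indication': 131,
 'excluded_no_followup': 34, 'kept': 2014} (2014, 1350)
```

— 2014 eligible decision points from 200 patients, 50 lab tests × 27 spaces
= 1350 feature columns. Training and evaluating on such features
(`examples/05_evaluate_with_bootstrap.py`, 250 patients, 10 tests) prints

```
 metric  point  boot_mean  ci_lower  ci_upper
roc_auc  0.811      0.811     0.773     0.849
 pr_auc  0.315      0.323     0.241     0.408
```

i.e. held-out decision points of unseen patients are ranked well above
chance, with the percentile CI quantifying test-set uncertainty. The
`examples/` directory holds one short script per capability (simulation,
labeling, featurization, selection, evaluation, full pipeline); the
`rdpredict` CLI exposes the same stages (`simulate`, `label`, `featurize`,
`train`, `evaluate`, `run`) driven by a YAML config.

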