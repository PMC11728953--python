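"""Train the gradient-boosted model and run recursive feature elimination.

Uses a reduced cohort and tree budget so the example finishes in about a
minute; the selection path shows how cross-validated performance varies
with the number of surviving features.
"""

import numpy as np
import pandas as pd

import rdpredict as rp

config = rp.GeneratorConfig(n_patients=150, n_tests=8, informative_tests=("LAB003",), seed=7)
patients, labs, _ = rp.generate_cohort(config)
indications = rp.label_cohort(labs)
windows = rp.StudyWindows(decision_end=pd.Timestamp(config.study_end) - pd.Timedelta(days=365))
decision_points, _ = rp.extract_decision_points(patients, indications, windows)
X, y = rp.build_feature_matrix(decision_points, labs, sorted(labs["test_code"].unique()))
groups = decision_points["patient_id"].to_numpy()

params = rp.ModelParams(n_estimators=120, min_child_samples=20, seed=7)
path = rp.run_rfecv(X, y.to_numpy(), groups, params, cv=3, keep_every=20)

scored = path.dropna(subset=["roc_auc"])
print("selection path (cross-validated, patient-grouped folds):")
print(scored[["n_features", "roc_auc", "pr_auc", "accuracy", "f1"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
best = scored.loc[scored["roc_auc"].idxmax()]
top = list(best["features"])[:8]
print(f"best size by ROC-AUC: {int(best['n_features'])} features")
print("examples of surviving features:", ", ".join(top))
print()
print("Performance plateaus while informative features remain and drops as")
print("elimination cuts into them — the shape used to pick a parsimonious")
print("model. eGFR/creatinine spaces typically dominate the survivors.")
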