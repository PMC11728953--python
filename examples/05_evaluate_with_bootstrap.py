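"""Hold out 30 % of patients, score the model and bootstrap the metrics.

Reports the six evaluation metrics with 95 % percentile bootstrap CIs from
resampling the test decision points, plus VIF diagnostics of a few selected
features.
"""

import numpy as np
import pandas as pd

import rdpredict as rp

config = rp.GeneratorConfig(n_patients=250, n_tests=10, informative_tests=("LAB003",), seed=3)
patients, labs, _ = rp.generate_cohort(config)
indications = rp.label_cohort(labs)
windows = rp.StudyWindows(decision_end=pd.Timestamp(config.study_end) - pd.Timedelta(days=365))
decision_points, _ = rp.extract_decision_points(patients, indications, windows)
X, y = rp.build_feature_matrix(decision_points, labs, sorted(labs["test_code"].unique()))
groups = decision_points["patient_id"].to_numpy()

train_ids, test_ids = rp.split_patients(groups, train_fraction=0.7, seed=3)
tr = np.isin(groups, train_ids)
print(f"patients: {len(train_ids)} train / {len(test_ids)} test (no overlap)")

params = rp.ModelParams(n_estimators=200, min_child_samples=20, seed=3)
model = rp.fit_classifier(X.loc[tr], y.to_numpy()[tr], params, groups=groups[tr])
scores = model.predict(X.loc[~tr])

report = rp.bootstrap_ci(scores, y.to_numpy()[~tr], B=1000, seed=3)
print()
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("Each row: point estimate on the held-out decision points, bootstrap")
print("mean and 95% percentile CI over 1000 row resamples.")

top = model.gain_importance().sort_values(ascending=False).head(4).index.tolist()
print()
print("VIF of the top-gain features (>10 would flag multicollinearity):")
print(rp.vif(X[top]).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
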