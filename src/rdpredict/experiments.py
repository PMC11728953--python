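"""Reproducible study-condition experiments.

Each function runs one self-contained check of the pipeline under the
package's reference study conditions — the synthetic-cohort defaults of
:class:`~rdpredict.synth.GeneratorConfig` (500 patients, 50 lab test codes
of which 3 beyond creatinine/eGFR are informative, 30 % planted
rapid-decline episodes, eGFR noise SD 3) — and returns plain numbers.  They
back both the acceptance checks in the test suite and the
``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import StudyWindows, extract_decision_points
from .evaluation import bootstrap_ci, compute_metrics, split_patients, vif
from .features import SpaceGrid, build_feature_matrix
from .labeling import RdCriteria, classify_indications, label_cohort
from .model import ModelParams, fit_classifier, rfe_schedule, run_rfecv
from .synth import GeneratorConfig, generate_cohort

__all__ = [
    "feature_count",
    "end_to_end_auc",
    "planted_signal_medians",
    "labeling_oracle_agreement",
    "rfecv_schedule_sizes",
    "rfecv_path_is_nested",
    "bootstrap_coverage",
    "bootstrap_width_ratio",
    "vif_sanity",
]


def feature_count(n_test_codes: int, grid: SpaceGrid = SpaceGrid()) -> int:
    """Number of feature columns produced for ``n_test_codes`` lab tests.

    Counted from an actually-built (empty) feature matrix, not from
    arithmetic on the grid.
    """
    codes = [f"T{i:04d}" for i in range(n_test_codes)]
    labs = pd.DataFrame(
        {
            "patient_id": "P0",
            "date": pd.Timestamp("2020-01-01"),
            "test_code": codes,
            "value": 1.0,
        }
    )
    dp = pd.DataFrame({"patient_id": [], "date": [], "label": []})
    X, _ = build_feature_matrix(dp, labs, codes, grid)
    return X.shape[1]


def _study_pipeline(seed: int, config: GeneratorConfig | None = None):
    """Generate, label, featurize and split one study-condition cohort."""
    cfg = (config or GeneratorConfig()).replace(seed=seed)
    patients, labs, _ = generate_cohort(cfg)
    indications = label_cohort(labs)
    windows = StudyWindows(
        decision_end=pd.Timestamp(cfg.study_end) - pd.Timedelta(days=365)
    )
    dp, _ = extract_decision_points(patients, indications, windows)
    X, y = build_feature_matrix(dp, labs, sorted(labs["test_code"].unique()))
    groups = dp["patient_id"].to_numpy()
    return X, y.to_numpy(), groups


def end_to_end_auc(seed: int, permute: bool = False) -> float:
    """Test-set ROC-AUC of the full pipeline on one seeded cohort.

    With ``permute=True`` the labels are randomly permuted before the
    patient split, destroying the signal while preserving prevalence — the
    resulting AUC should hover around chance.
    """
    X, y, groups = _study_pipeline(seed)
    if permute:
        y = np.random.default_rng(seed).permutation(y)
    train_ids, _ = split_patients(groups, 0.7, seed)
    tr = np.isin(groups, train_ids)
    params = ModelParams(seed=seed)
    model = fit_classifier(X.loc[tr], y[tr], params, groups=groups[tr])
    scores = model.predict(X.loc[~tr])
    return compute_metrics(scores, y[~tr])["roc_auc"]


def planted_signal_medians(n_seeds: int = 20, base_seed: int = 0) -> dict[str, float]:
    """Median real and label-permuted test ROC-AUC over seeded cohorts."""
    real, permuted = [], []
    for i in range(n_seeds):
        seed = (base_seed * 1009 + i) % (2**31 - 1)
        real.append(end_to_end_auc(seed, permute=False))
        permuted.append(end_to_end_auc(seed, permute=True))
    return {
        "median_roc_auc": float(np.median(real)),
        "median_roc_auc_permuted": float(np.median(permuted)),
    }


def labeling_oracle_agreement(n_series: int = 200, seed: int = 0) -> float:
    """Fraction of test dates where the RD classifier matches the oracle.

    Draws noise-free piecewise-linear eGFR trajectories and compares
    :func:`classify_indications` (criterion on raw values, where smoothing
    is an exact identity) against a direct analytic evaluation of the drop
    criterion; exact agreement gives 1.0.
    """
    rng = np.random.default_rng(seed)
    agree = total = 0
    crit = RdCriteria(on_smoothed=False)
    for _ in range(n_series):
        n = int(rng.integers(5, 40))
        days = np.sort(rng.choice(np.arange(1400), size=n, replace=False)).astype(float)
        baseline = rng.uniform(45.0, 95.0)
        s1 = rng.uniform(-6.0, 1.0) / 365.0
        s2 = rng.uniform(-15.0, -2.0) / 365.0
        knee = rng.uniform(200.0, 1200.0)
        values = np.where(
            days <= knee, baseline + s1 * days, baseline + s1 * knee + s2 * (days - knee)
        )
        values = np.maximum(values, 1.0)
        res = classify_indications(days, values, crit)
        flags = res["rd_flag"].to_numpy()
        expect = _oracle_flags(days, values, crit)
        agree += int(np.sum(flags == expect))
        total += n
    return agree / total


def _oracle_flags(days: np.ndarray, values: np.ndarray, crit: RdCriteria) -> np.ndarray:
    out = []
    for i, t in enumerate(days):
        t_ref = t - crit.lookback_days
        if t_ref < days[0]:
            out.append(False)
            continue
        ref = float(np.interp(t_ref, days, values))
        out.append(
            values[i] < crit.egfr_threshold and ref - values[i] >= crit.drop_threshold
        )
    return np.array(out, dtype=bool)


def rfecv_schedule_sizes(n_features: int = 100) -> list[int]:
    return rfe_schedule(n_features)


def rfecv_path_is_nested(seed: int = 0, n_features: int = 100) -> bool:
    """Run the eliminator from ``n_features`` synthetic columns and check
    that every visited subset nests inside the previous one and the visited
    sizes follow the schedule."""
    rng = np.random.default_rng(seed)
    n = 300
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)), columns=[f"f{i}" for i in range(n_features)]
    )
    logit = X.iloc[:, :3].sum(axis=1) * 2.0
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).to_numpy().astype(int)
    groups = np.arange(n) // 3
    params = ModelParams(
        n_estimators=30, min_child_samples=5, num_leaves=15, lambda_l1=0.0, lambda_l2=0.0,
        feature_fraction=1.0, seed=seed,
    )
    path = run_rfecv(X, y, groups, params, cv=0)
    if list(path["n_features"]) != rfe_schedule(n_features):
        return False
    sets = [set(f) for f in path["features"]]
    return all(b < a for a, b in zip(sets, sets[1:]))


def _synthetic_scored_set(rng: np.random.Generator, n: int):
    labels = (rng.random(n) < 0.3).astype(int)
    scores = np.clip(rng.normal(0.35 + 0.3 * labels, 0.2), 1e-3, 1 - 1e-3)
    # guarantee both classes so AUCs are defined
    labels[0], labels[1] = 0, 1
    return scores, labels


def bootstrap_coverage(
    n_sets: int = 100, n: int = 250, B: int = 1000, seed: int = 0, metric: str = "roc_auc"
) -> int:
    """Number of synthetic test sets whose 95 % percentile CI brackets the
    plug-in estimate of ``metric``."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_sets):
        scores, labels = _synthetic_scored_set(rng, n)
        rep = bootstrap_ci(scores, labels, B=B, seed=int(rng.integers(2**31 - 1)))
        if rep.lower[metric] <= rep.point[metric] <= rep.upper[metric]:
            hits += 1
    return hits


def bootstrap_width_ratio(
    n: int = 300, B: int = 1000, reps: int = 8, seed: int = 0, metric: str = "roc_auc"
) -> float:
    """Mean CI width at sample size 2n over mean width at n.

    Bootstrap CI width scales roughly like 1/sqrt(sample size), so the
    ratio should sit near 1/sqrt(2) ~ 0.71.
    """
    rng = np.random.default_rng(seed)
    widths = {n: [], 2 * n: []}
    for _ in range(reps):
        for size in (n, 2 * n):
            scores, labels = _synthetic_scored_set(rng, size)
            rep = bootstrap_ci(scores, labels, B=B, seed=int(rng.integers(2**31 - 1)))
            widths[size].append(rep.upper[metric] - rep.lower[metric])
    return float(np.mean(widths[2 * n]) / np.mean(widths[n]))


def vif_sanity(seed: int = 0, n: int = 10_000) -> dict[str, float]:
    """VIF of two independent features and of a near-duplicated pair."""
    rng = np.random.default_rng(seed)
    indep = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
    a = rng.normal(size=2000)
    dup = pd.DataFrame({"a": a, "dup": a + rng.normal(0, 1e-4, 2000)})
    return {
        "independent_max_vif": float(vif(indep)["vif"].max()),
        "duplicated_min_vif": float(vif(dup)["vif"].min()),
    }
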