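"""Gradient-boosted-tree classifier and recursive feature elimination.

The learner is a leaf-wise gradient-boosted decision-tree ensemble
(LightGBM) with native missing-value routing, trained with cross-entropy
loss and early stopping on validation PR-AUC.  Five regularization
parameters (bagging_fraction, bagging_freq, feature_fraction, lambda_l1,
lambda_l2) are tunable via a seeded random search maximizing patient-grouped
cross-validated PR-AUC.  Recursive feature elimination removes 5 % of the
current features per iteration (by gain importance, lowest first) while more
than 40 remain, then one feature at a time down to a single feature,
recording patient-grouped cross-validated metrics at every size.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluation import compute_metrics

__all__ = [
    "ModelParams",
    "FittedModel",
    "fit_classifier",
    "tune_hyperparameters",
    "run_rfecv",
    "grouped_stratified_folds",
]

logger = logging.getLogger(__name__)

#: Names of the five parameters exposed to hyperparameter search.
TUNABLE_PARAMS = ("bagging_fraction", "bagging_freq", "feature_fraction", "lambda_l1", "lambda_l2")


@dataclass
class ModelParams:
    """LightGBM configuration for RD prediction.

    Fixed regime: learning_rate 0.05, max_depth 10, num_leaves 50,
    min_child_samples 100, up to 1000 boosting rounds with cross-entropy
    loss, early stopping after 50 rounds without PR-AUC improvement,
    classification threshold 0.5, gain feature importance.  The five
    entries of :data:`TUNABLE_PARAMS` are the search space of
    :func:`tune_hyperparameters`.
    """

    learning_rate: float = 0.05
    max_depth: int = 10
    num_leaves: int = 50
    min_child_samples: int = 100
    n_estimators: int = 1000
    early_stopping_rounds: int = 50
    threshold: float = 0.5
    bagging_fraction: float = 1.0
    bagging_freq: int = 0
    feature_fraction: float = 0.852
    lambda_l1: float = 9.998
    lambda_l2: float = 2.561
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def to_lightgbm(self) -> dict:
        return {
            "objective": "cross_entropy",
            "metric": "average_precision",
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "num_leaves": self.num_leaves,
            "min_child_samples": self.min_child_samples,
            "bagging_fraction": self.bagging_fraction,
            "bagging_freq": self.bagging_freq,
            "feature_fraction": self.feature_fraction,
            "lambda_l1": self.lambda_l1,
            "lambda_l2": self.lambda_l2,
            "n_estimators": self.n_estimators,
            "deterministic": True,
            "force_col_wise": True,
            "num_threads": 1,
            "seed": self.seed,
            "verbosity": -1,
        }

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass
class FittedModel:
    """A trained booster plus the column order it was trained with."""

    booster: lgb.Booster
    feature_names: list[str]
    threshold: float = 0.5
    best_iteration: int | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Scores in [0, 1] (probability of RD within the event window)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        scores = self.booster.predict(X, num_iteration=self.best_iteration)
        return np.clip(np.asarray(scores, dtype=float), 0.0, 1.0)

    def classify(self, X) -> np.ndarray:
        return self.predict(X) >= self.threshold

    def gain_importance(self) -> pd.Series:
        imp = self.booster.feature_importance(importance_type="gain")
        return pd.Series(imp, index=self.feature_names, name="gain")


def fit_classifier(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    params: ModelParams = ModelParams(),
    groups: np.ndarray | pd.Series | None = None,
    valid: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> FittedModel:
    """Train the booster with early stopping on validation PR-AUC.

    When ``valid`` is given it is used as the early-stopping set.  Otherwise,
    if ``groups`` (patient ids per row) are given, 20 % of the training
    patients are held out for early stopping so no patient straddles the
    split.  With neither, training runs the full ``n_estimators`` rounds.

    Raises ``ValueError`` when the training labels contain a single class.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class; cannot fit a classifier")
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(X.shape[1])
    ]
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)

    eval_set = None
    if valid is not None:
        Xv, yv = valid
        Xv = Xv.to_numpy(dtype=float) if isinstance(Xv, pd.DataFrame) else np.asarray(Xv, float)
        eval_set = (Xv, np.asarray(yv, dtype=int))
    elif groups is not None:
        tr, va = _holdout_by_group(np.asarray(groups), y, params.validation_fraction, params.seed)
        if va.size and np.unique(y[va]).size == 2:
            eval_set = (Xa[va], y[va])
            Xa, y = Xa[tr], y[tr]
            if np.unique(y).size < 2:
                raise ValueError("early-stopping split left a single-class training set")

    lgb_params = params.to_lightgbm()
    n_rounds = lgb_params.pop("n_estimators")
    train_set = lgb.Dataset(Xa, label=y, feature_name=feature_names, free_raw_data=True)
    kwargs: dict = {}
    if eval_set is not None:
        kwargs["valid_sets"] = [lgb.Dataset(eval_set[0], label=eval_set[1], reference=train_set)]
        kwargs["callbacks"] = [lgb.early_stopping(params.early_stopping_rounds, verbose=False)]
    booster = lgb.train(lgb_params, train_set, num_boost_round=n_rounds, **kwargs)
    best_it = booster.best_iteration if eval_set is not None and booster.best_iteration else None
    return FittedModel(booster, feature_names, params.threshold, best_it)


def _holdout_by_group(
    groups: np.ndarray, y: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices for a (train, validation) split holding out whole groups."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    n_val = max(1, int(round(fraction * uniq.size)))
    val_groups = set(perm[:n_val].tolist())
    mask = np.fromiter((g in val_groups for g in groups), dtype=bool, count=groups.size)
    return np.nonzero(~mask)[0], np.nonzero(mask)[0]


def grouped_stratified_folds(
    groups: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    n_splits: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped CV folds, stratified by patient-level label.

    A patient's label is positive when any of their decision points is
    positive; patients are stratified into folds and each fold's row indices
    are the union of its patients' rows, so no patient appears on both sides
    of any fold.
    """
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=int)
    uniq, inv = np.unique(groups, return_inverse=True)
    pat_label = np.zeros(uniq.size, dtype=int)
    np.maximum.at(pat_label, inv, y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = []
    for tr_pat, va_pat in skf.split(uniq, pat_label):
        tr_mask = np.isin(inv, tr_pat)
        folds.append((np.nonzero(tr_mask)[0], np.nonzero(~tr_mask)[0]))
    return folds


def _cv_mean_metrics(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    params: ModelParams,
    n_splits: int,
) -> dict[str, float]:
    """Mean of the six metrics over grouped stratified CV folds."""
    names = ["roc_auc", "pr_auc", "accuracy", "recall", "precision", "f1"]
    acc: dict[str, list[float]] = {m: [] for m in names}
    for tr, va in grouped_stratified_folds(groups, y, n_splits, params.seed):
        if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
            continue
        model = fit_classifier(X.iloc[tr], y[tr], params, groups=groups[tr])
        scores = model.predict(X.iloc[va])
        m = compute_metrics(scores, y[va], params.threshold)
        for name in names:
            acc[name].append(m[name])
    if not acc["roc_auc"]:
        raise ValueError("no usable CV fold (single-class folds everywhere)")
    return {name: float(np.mean(vals)) for name, vals in acc.items()}


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    params: ModelParams = ModelParams(),
    n_trials: int = 100,
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Seeded random search over the five tunable parameters.

    Trial 0 evaluates the incoming defaults; subsequent trials draw
    bagging_fraction ~ U(0.5, 1), bagging_freq ~ U{0..7},
    feature_fraction ~ U(0.4, 1) and the two lambda penalties
    log-uniformly from [1e-8, 10].  The objective is mean PR-AUC over
    patient-grouped stratified CV.  Returns ``(best_values, trials_table)``;
    identical seeds reproduce identical selections.
    """
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    records = []
    best_val, best_cfg = -np.inf, None
    for trial in range(max(1, n_trials)):
        if trial == 0:
            cand = {name: getattr(params, name) for name in TUNABLE_PARAMS}
        else:
            cand = {
                "bagging_fraction": float(rng.uniform(0.5, 1.0)),
                "bagging_freq": int(rng.integers(0, 8)),
                "feature_fraction": float(rng.uniform(0.4, 1.0)),
                "lambda_l1": float(10 ** rng.uniform(-8, 1)),
                "lambda_l2": float(10 ** rng.uniform(-8, 1)),
            }
        trial_params = params.replace(**cand)
        score = _cv_mean_metrics(X, y, groups, trial_params, n_splits)["pr_auc"]
        records.append({"trial": trial, **cand, "pr_auc": score})
        if score > best_val:
            best_val, best_cfg = score, cand
    logger.info("hyperparameter search: best PR-AUC %.4f with %s", best_val, best_cfg)
    return best_cfg, pd.DataFrame(records)


def rfe_schedule(n_features: int, coarse_cutoff: int = 40, coarse_rate: float = 0.05) -> list[int]:
    """Feature-count sequence for recursive elimination.

    While more than ``coarse_cutoff`` features remain, each step removes
    ``floor(coarse_rate * n_features)`` features (5 % of the starting count,
    rounded down, at least 1) — so from 100 features the sequence runs
    100, 95, 90, … .  At or below the cutoff exactly one feature is removed
    per step, down to a single feature.
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    coarse = max(1, math.floor(coarse_rate * n_features))
    sizes = [n_features]
    n = n_features
    while n > 1:
        removed = coarse if n > coarse_cutoff else 1
        n = max(1, n - removed)
        sizes.append(n)
    return sizes


def run_rfecv(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    params: ModelParams = ModelParams(),
    cv: int = 5,
    keep_every: int = 1,
) -> pd.DataFrame:
    """Recursive feature elimination with grouped cross-validation.

    At each size of :func:`rfe_schedule` the model is fitted on the full
    training data (with a patient-held-out early-stopping split), features
    are ranked by gain importance with ties broken by stable column order,
    and the lowest-ranked are dropped.  With ``cv >= 2`` the six
    cross-validated metrics are recorded at every ``keep_every``-th size
    (and always at the first and last); ``cv = 0`` records the selection
    path only, which is much cheaper.

    Returns the *selection path*: one row per visited size with columns
    ``n_features``, ``features`` (tuple, preserving column order),
    ``roc_auc`` … ``f1`` (NaN when not evaluated).  Feature sets are nested
    along the path.
    """
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    current = list(X.columns)
    sizes = rfe_schedule(len(current))
    records = []
    for step, size in enumerate(sizes):
        assert len(current) == size
        sub = X[current]
        metrics = {m: np.nan for m in ["roc_auc", "pr_auc", "accuracy", "recall", "precision", "f1"]}
        if cv >= 2 and (step % keep_every == 0 or size == sizes[-1] or step == 0):
            metrics = _cv_mean_metrics(sub, y, groups, params, cv)
        records.append({"n_features": size, "features": tuple(current), **metrics})
        if size == 1:
            break
        model = fit_classifier(sub, y, params, groups=groups)
        imp = model.gain_importance().to_numpy()
        n_remove = size - sizes[step + 1]
        # stable argsort: among equal importances the earlier column goes first
        order = np.argsort(imp, kind="stable")
        drop = {current[i] for i in order[:n_remove]}
        current = [c for c in current if c not in drop]
    return pd.DataFrame(records)
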