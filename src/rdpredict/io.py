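"""Table formats, run configuration and pipeline orchestration.

The pipeline ties the stages — simulate (or load), label, cohort, featurize,
split, tune, select, evaluate — into one seeded, reproducible run that
writes every report table plus the resolved configuration to an output
directory.  All tables are plain CSV; the feature matrix documents its
missing-value convention (empty cell = missing) in a ``#`` header line so
round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import StudyWindows, extract_decision_points
from .evaluation import bootstrap_ci, characteristics_table, split_patients, vif
from .features import SpaceGrid, build_feature_matrix
from .labeling import RdCriteria, label_cohort
from .model import ModelParams, fit_classifier, run_rfecv, tune_hyperparameters
from .synth import GeneratorConfig, generate_cohort

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_lab_table",
    "read_patient_table",
    "write_feature_matrix",
    "read_feature_matrix",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

LAB_COLUMNS = ["patient_id", "date", "test_code", "value"]
PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "dialysis_date", "transplant_date"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, in one place.

    When ``lab_table``/``patient_table`` paths are set the pipeline loads
    them; otherwise it simulates a cohort from ``generator``.  The resolved
    config is serialized next to the outputs for provenance.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    criteria: RdCriteria = field(default_factory=RdCriteria)
    windows: StudyWindows = field(default_factory=StudyWindows)
    grid: SpaceGrid = field(default_factory=SpaceGrid)
    model: ModelParams = field(default_factory=ModelParams)
    lab_table: str | None = None
    patient_table: str | None = None
    train_fraction: float = 0.7
    tune_enabled: bool = False
    tune_trials: int = 100
    rfecv_enabled: bool = True
    cv_folds: int = 5
    cv_keep_every: int = 1
    final_n_features: int | None = None
    bootstrap_resamples: int = 1000
    bootstrap_unit: str = "decision_point"
    seed: int = 0
    output_dir: str = "rdpredict_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["informative_tests"] = list(d["generator"]["informative_tests"])
        for key in ("decision_start", "decision_end"):
            v = d["windows"][key]
            d["windows"][key] = None if v is None else str(pd.Timestamp(v).date())
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "generator": GeneratorConfig,
            "criteria": RdCriteria,
            "windows": StudyWindows,
            "grid": SpaceGrid,
            "model": ModelParams,
        }
        kwargs = {}
        for key, typ in sub.items():
            payload = dict(d.pop(key, {}) or {})
            if key == "generator" and "informative_tests" in payload:
                payload["informative_tests"] = tuple(payload["informative_tests"])
            if key == "windows":
                for dk in ("decision_start", "decision_end"):
                    if payload.get(dk) is not None:
                        payload[dk] = pd.Timestamp(payload[dk])
            kwargs[key] = typ(**payload)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs, **{k: v for k, v in d.items() if k in known})


def read_lab_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format lab observation CSV.

    Requires columns patient_id, date, test_code, value; dates are parsed
    as ISO-8601 and rows whose value does not parse as a number are dropped
    with a logged count.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "test_code": str})
    for col in LAB_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"lab table missing required column: {col!r}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna() | df["value"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("read_lab_table: rejected %d rows with unparseable values", n_bad)
    df = df.loc[~bad].copy()
    df["value"] = values.loc[~bad]
    return df[LAB_COLUMNS].reset_index(drop=True)


def read_patient_table(path: str | Path) -> pd.DataFrame:
    """Read the patient roster CSV (dates ISO-8601; blanks become NaT)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    for col in ("patient_id",):
        if col not in df.columns:
            raise ValueError(f"patient table missing required column: {col!r}")
    for col in ("birth_date", "dialysis_date", "transplant_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        else:
            df[col] = pd.NaT
    return df


def write_feature_matrix(path: str | Path, X: pd.DataFrame, y: pd.Series) -> None:
    """Persist the feature matrix with labels; empty cells encode missing."""
    out = X.copy()
    out.insert(0, "label", y.astype(int).to_numpy())
    with open(path, "w") as fh:
        fh.write("# rdpredict feature matrix; empty cell = missing value\n")
        out.to_csv(fh, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, comment="#")
    y = df.pop("label").astype(bool)
    return df, y.rename("label")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Emits, under ``config.output_dir``: the (simulated or loaded) input
    tables, the indication table, decision-point table, feature matrix,
    selection path (the performance-vs-feature-count curve data), the
    bootstrap metric report, VIF table, characteristics table and the
    resolved config.  Identical configs and seeds give identical reports.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    patients, labs, ground_truth = _stage("input")(_load_inputs)(config)
    report["patients"], report["labs"] = patients, labs
    if ground_truth is not None:
        ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    labs.to_csv(outdir / "lab_observations.csv", index=False)

    indications = _stage("labeling")(label_cohort)(labs, config.criteria)
    report["indications"] = indications
    indications.to_csv(outdir / "indications.csv", index=False)

    windows = config.windows
    if windows.decision_end is None:
        end = pd.Timestamp(config.generator.study_end) - pd.Timedelta(
            days=windows.event_window_days
        )
        windows = dataclasses.replace(windows, decision_end=end)
    dp, counts = _stage("cohort")(extract_decision_points)(patients, indications, windows)
    report["decision_points"], report["exclusion_counts"] = dp, counts
    dp.to_csv(outdir / "decision_points.csv", index=False)

    test_codes = sorted(labs["test_code"].unique())
    X, y = _stage("features")(build_feature_matrix)(dp, labs, test_codes, config.grid)
    report["X"], report["y"] = X, y
    write_feature_matrix(outdir / "feature_matrix.csv", X, y)

    groups = dp["patient_id"].to_numpy()
    train_ids, test_ids = _stage("split")(split_patients)(
        groups, config.train_fraction, config.seed
    )
    tr = np.isin(groups, train_ids)
    Xtr, ytr, gtr = X.loc[tr], y.to_numpy()[tr], groups[tr]
    Xte, yte = X.loc[~tr], y.to_numpy()[~tr]
    report["n_train_patients"], report["n_test_patients"] = len(train_ids), len(test_ids)

    params = config.model.replace(seed=config.seed)
    if config.tune_enabled:
        best, trials = _stage("tuning")(tune_hyperparameters)(
            Xtr, ytr, gtr, params, config.tune_trials, config.cv_folds, config.seed
        )
        params = params.replace(**best)
        trials.to_csv(outdir / "tuning_trials.csv", index=False)
        report["tuning"] = trials

    selected = list(X.columns)
    if config.rfecv_enabled:
        path = _stage("selection")(run_rfecv)(
            Xtr, ytr, gtr, params, config.cv_folds, config.cv_keep_every
        )
        report["selection_path"] = path
        curve = path.drop(columns=["features"])
        curve.to_csv(outdir / "selection_path.csv", index=False)
        selected = _pick_feature_set(path, config.final_n_features)
    report["selected_features"] = selected

    model = _stage("model")(fit_classifier)(Xtr[selected], ytr, params, groups=gtr)
    report["model"] = model
    scores = model.predict(Xte[selected])
    metrics = _stage("evaluation")(bootstrap_ci)(
        scores,
        yte,
        B=config.bootstrap_resamples,
        seed=config.seed,
        threshold=params.threshold,
        unit=config.bootstrap_unit,
        groups=groups[~tr],
    )
    report["metrics"] = metrics
    metrics.to_frame().to_csv(outdir / "metric_report.csv", index=False)

    vif_table = _stage("vif")(_safe_vif)(pd.concat([Xtr[selected], Xte[selected]]))
    report["vif"] = vif_table
    if vif_table is not None:
        vif_table.to_csv(outdir / "vif_table.csv", index=False)

    bins = {c: _default_bins(X[c]) for c in selected}
    chars = _stage("characteristics")(characteristics_table)(X[selected], y.to_numpy(), bins)
    report["characteristics"] = chars
    chars.to_csv(outdir / "characteristics_table.csv", index=False)

    cfg = dataclasses.replace(config)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    logger.info("pipeline complete: %d decision points, %d selected features", len(dp), len(selected))
    return report


def _load_inputs(config: RunConfig):
    if config.lab_table and config.patient_table:
        return read_patient_table(config.patient_table), read_lab_table(config.lab_table), None
    patients, labs, gt = generate_cohort(config.generator.replace(seed=config.seed))
    return patients, labs, gt


def _pick_feature_set(path: pd.DataFrame, n_features: int | None) -> list[str]:
    if n_features is not None:
        row = path[path["n_features"] == n_features]
        if row.empty:
            raise ValueError(f"selection path has no subset of size {n_features}")
        return list(row.iloc[0]["features"])
    scored = path.dropna(subset=["roc_auc"])
    if scored.empty:
        return list(path.iloc[0]["features"])
    best = scored.loc[scored["roc_auc"].idxmax()]
    return list(best["features"])


def _safe_vif(X: pd.DataFrame) -> pd.DataFrame | None:
    try:
        return vif(X)
    except ValueError as exc:
        logger.warning("VIF skipped: %s", exc)
        return None


def _default_bins(col: pd.Series) -> list[float]:
    """Tertile cut points of the pooled non-missing values."""
    vals = col.dropna()
    if vals.empty:
        return []
    q = np.quantile(vals, [1 / 3, 2 / 3])
    return sorted(set(float(x) for x in q))
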