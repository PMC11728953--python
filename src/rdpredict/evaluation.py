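"""Holdout split, classifier metrics, bootstrap CIs, VIF and cohort tables.

Evaluation follows a patient-level holdout: patients (not decision points)
are split 70/30 so no patient contributes rows to both sides.  Test-set
metrics are reported with 95 % percentile bootstrap confidence intervals
from 1000 row resamples.  Multicollinearity of the selected features is
diagnosed with variance inflation factors, and the cohort-characteristics
table compares RD and not_RD decision points with Mann-Whitney U tests
(continuous values) and Fisher exact tests (bins and missingness).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "split_patients",
    "compute_metrics",
    "MetricReport",
    "bootstrap_ci",
    "vif",
    "fisher_exact_2xk",
    "characteristics_table",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("roc_auc", "pr_auc", "accuracy", "recall", "precision", "f1")


def split_patients(
    patient_ids, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random patient-level 70/30 split.

    The test side receives ``ceil((1 - train_fraction) * n)`` patients, so
    3438 patients split into 2406 train / 1032 test.  The two sides are
    disjoint and exhaust the input.
    """
    ids = np.asarray(pd.unique(np.asarray(patient_ids)))
    n = ids.size
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_test = math.ceil(round((1.0 - train_fraction) * n, 9))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(ids)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    allow_single_class: bool = False,
) -> dict[str, float]:
    """The six evaluation metrics at a fixed classification threshold.

    ROC-AUC by trapezoidal integration over thresholds (the tie-aware rank
    form); PR-AUC as the area under the precision-recall curve (average
    precision, the step-function estimator); accuracy, recall, precision
    and F1 at ``threshold``, with zero returned for ratios whose
    denominator is zero.  Single-class labels make the AUCs undefined: by
    default that raises, with ``allow_single_class=True`` the AUCs are
    returned as NaN and the threshold metrics still computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    single = n_pos == 0 or n_pos == labels.size
    if single and not allow_single_class:
        raise ValueError("labels contain a single class; ROC-AUC and PR-AUC are undefined")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_pos if n_pos else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "roc_auc": np.nan if single else _roc_auc(scores, labels, n_pos),
        "pr_auc": np.nan if single else _average_precision(scores, labels, n_pos),
        "accuracy": float(np.mean(pred == (labels == 1))),
        "recall": recall,
        "precision": precision,
        "f1": f1,
    }


def _roc_auc(scores: np.ndarray, labels: np.ndarray, n_pos: int) -> float:
    """Rank-statistic ROC-AUC with midranks for ties (equals the trapezoid
    area under the empirical ROC curve)."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    ranks = np.empty(s.size)
    i = 0
    while i < s.size:  # midranks over tied score groups
        j = i
        while j + 1 < s.size and s[j + 1] == s[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_neg = labels.size - n_pos
    rank_sum = float(np.sum(ranks[labels[order] == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _average_precision(scores: np.ndarray, labels: np.ndarray, n_pos: int) -> float:
    """Step-function area under the precision-recall curve: sum of
    precision times incremental recall over descending score thresholds,
    with tied scores grouped."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    boundaries = np.nonzero(np.diff(s))[0]  # last index of each tie group
    idx = np.concatenate([boundaries, [s.size - 1]])
    tp = np.cumsum(y)[idx].astype(float)
    n_at = idx + 1.0
    prec = tp / n_at
    d_tp = np.diff(np.concatenate([[0.0], tp]))
    return float(np.sum(prec * d_tp) / n_pos)


@dataclass
class MetricReport:
    """Point estimates plus bootstrap mean and 95 % percentile CI."""

    point: dict[str, float]
    mean: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    n_resamples: int
    n_redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": m,
                "point": self.point[m],
                "boot_mean": self.mean[m],
                "ci_lower": self.lower[m],
                "ci_upper": self.upper[m],
            }
            for m in METRIC_NAMES
        ]
        return pd.DataFrame(rows)


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    threshold: float = 0.5,
    unit: str = "decision_point",
    groups: np.ndarray | None = None,
) -> MetricReport:
    """Percentile bootstrap over the test set.

    Rows (decision points) are resampled with replacement to the original
    size ``B`` times; each metric's bootstrap mean and
    ``[alpha/2, 1-alpha/2]`` percentile bounds are reported.  Resamples
    lacking one of the classes are redrawn for the AUC metrics (the count is
    kept in ``n_redraws``).  With ``unit="patient"`` whole patients
    (``groups``) are resampled instead, acknowledging within-patient
    correlation of decision points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = scores.size
    if n < 2 or np.unique(labels).size < 2:
        raise ValueError("bootstrap needs >= 2 rows with both classes present")
    rng = np.random.default_rng(seed)
    if unit == "patient":
        if groups is None:
            raise ValueError('unit="patient" requires groups')
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        rows_of = {g: np.nonzero(groups == g)[0] for g in uniq}
    elif unit != "decision_point":
        raise ValueError(f"unknown bootstrap unit: {unit!r}")

    point = compute_metrics(scores, labels, threshold)
    samples = {m: np.empty(B) for m in METRIC_NAMES}
    n_redraws = 0
    for b in range(B):
        idx = _resample(rng, n, unit, uniq if unit == "patient" else None, rows_of if unit == "patient" else None)
        m = compute_metrics(scores[idx], labels[idx], threshold, allow_single_class=True)
        if np.unique(labels[idx]).size < 2:
            # redraw until both classes present, for the AUC metrics only
            for _ in range(1000):
                n_redraws += 1
                idx2 = _resample(rng, n, unit, uniq if unit == "patient" else None, rows_of if unit == "patient" else None)
                if np.unique(labels[idx2]).size == 2:
                    m2 = compute_metrics(scores[idx2], labels[idx2], threshold)
                    m["roc_auc"], m["pr_auc"] = m2["roc_auc"], m2["pr_auc"]
                    break
            else:  # pragma: no cover - pathological label mix
                raise RuntimeError("could not draw a two-class bootstrap resample")
        for name in METRIC_NAMES:
            samples[name][b] = m[name]
    mean = {m: float(np.mean(samples[m])) for m in METRIC_NAMES}
    lo = {m: float(np.percentile(samples[m], 100 * alpha / 2)) for m in METRIC_NAMES}
    hi = {m: float(np.percentile(samples[m], 100 * (1 - alpha / 2))) for m in METRIC_NAMES}
    if n_redraws:
        logger.info("bootstrap: %d single-class resamples redrawn for AUCs", n_redraws)
    return MetricReport(point, mean, lo, hi, B, n_redraws)


def _resample(rng, n, unit, uniq=None, rows_of=None) -> np.ndarray:
    if unit == "decision_point":
        return rng.integers(0, n, size=n)
    chosen = rng.choice(uniq, size=uniq.size, replace=True)
    return np.concatenate([rows_of[g] for g in chosen])


def vif(X: pd.DataFrame, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factors of the selected feature columns.

    Complete cases only (rows with any missing selected feature are
    dropped).  For each feature j, ``VIF_j = 1 / (1 - R^2_j)`` where
    ``R^2_j`` comes from the least-squares regression of feature j on the
    remaining features plus an intercept.  A lone feature regressed on the
    intercept alone has VIF exactly 1.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    Z = X.dropna(axis=0)
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"fewer complete rows ({n}) than features + 1 ({p + 1})")
    A = Z.to_numpy(dtype=float)
    out = []
    for j in range(p):
        yj = A[:, j]
        others = np.delete(A, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0.0:
            v = np.nan  # constant feature: VIF undefined
        else:
            r2 = 1.0 - float(np.sum(resid**2)) / sst
            v = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        out.append({"feature": Z.columns[j], "vif": v, "high_multicollinearity": bool(v > flag_threshold)})
    return pd.DataFrame(out)


def fisher_exact_2xk(table: np.ndarray, max_tables: int = 500_000) -> float:
    """Two-sided Fisher exact p-value for a 2 x k contingency table.

    k = 2 delegates to the standard hypergeometric test; larger k uses the
    Freeman–Halton extension, enumerating all tables with the observed
    margins and summing the probabilities of tables no more probable than
    the observed one.  Raises when the enumeration would exceed
    ``max_tables`` (callers fall back to chi-square there).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    k = t.shape[1]
    if k == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    n_tables_bound = int(np.prod(col + 1.0))
    if n_tables_bound > max_tables:
        raise ValueError(f"enumeration too large ({n_tables_bound} candidate tables)")
    lgam = math.lgamma
    const = lgam(row[0] + 1) + lgam(row[1] + 1) - lgam(row.sum() + 1) + sum(
        lgam(c + 1) for c in col
    )

    def log_prob(first_row: tuple[int, ...]) -> float:
        s = const
        for x, c in zip(first_row, col):
            s -= lgam(x + 1) + lgam(c - x + 1)
        return s

    obs_lp = log_prob(tuple(t[0]))
    total = 0.0
    p_sum = 0.0

    def recurse(j: int, remaining: int, acc: list[int]):
        nonlocal total, p_sum
        if j == k - 1:
            if remaining > col[-1]:
                return
            lp = log_prob(tuple(acc + [remaining]))
            pr = math.exp(lp)
            total += pr
            if lp <= obs_lp + 1e-9:
                p_sum += pr
            return
        for x in range(min(col[j], remaining) + 1):
            recurse(j + 1, remaining - x, acc + [x])

    recurse(0, int(row[0]), [])
    return float(min(1.0, p_sum / total))  # normalize away rounding drift


def characteristics_table(
    X: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    bins: dict[str, list[float]] | None = None,
    max_exact_k: int = 5,
) -> pd.DataFrame:
    """Cohort-characteristics comparison of RD vs not_RD decision points.

    For every column of ``X``: mean (SD) per label group with a two-sided
    Mann-Whitney U p-value on the non-missing values; missing counts per
    group with a Fisher exact p-value; and, when ``bins`` provides cut
    points for the column, per-bin frequency counts with a Fisher exact
    p-value (Freeman–Halton for 2 x k bins when the enumeration is small
    and ``k <= max_exact_k``, otherwise a chi-square fallback with a logged
    warning).  No multiple-testing correction is applied.

    Returns a long-format table: feature, statistic, group summaries and
    p-value — one block per feature, mirroring a clinical Table-1 layout.
    """
    y = np.asarray(labels, dtype=bool)
    bins = bins or {}
    rows = []
    for colname in X.columns:
        col = X[colname].to_numpy(dtype=float)
        pos, neg = col[y], col[~y]
        pos_ok, neg_ok = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
        if pos_ok.size and neg_ok.size:
            p_mw = float(stats.mannwhitneyu(pos_ok, neg_ok, alternative="two-sided")[1])
        else:
            p_mw = np.nan
        rows.append(
            {
                "feature": colname,
                "statistic": "mean (SD)",
                "rd": f"{pos_ok.mean():.2f} ({pos_ok.std(ddof=1):.2f})" if pos_ok.size > 1 else "—",
                "not_rd": f"{neg_ok.mean():.2f} ({neg_ok.std(ddof=1):.2f})" if neg_ok.size > 1 else "—",
                "p_value": p_mw,
            }
        )
        miss_tab = np.array(
            [[int(np.isnan(pos).sum()), int(np.isnan(neg).sum())],
             [int((~np.isnan(pos)).sum()), int((~np.isnan(neg)).sum())]]
        )
        p_miss = _fisher_or_chi2(miss_tab.T, max_exact_k)
        rows.append(
            {
                "feature": colname,
                "statistic": "missing, n",
                "rd": str(int(np.isnan(pos).sum())),
                "not_rd": str(int(np.isnan(neg).sum())),
                "p_value": p_miss,
            }
        )
        if colname in bins:
            edges = [-np.inf] + list(bins[colname]) + [np.inf]
            tab = np.zeros((2, len(edges) - 1), dtype=int)
            for gi, grp in enumerate((pos_ok, neg_ok)):
                tab[gi] = np.histogram(grp, bins=edges)[0]
            keep = tab.sum(axis=0) > 0
            p_bins = _fisher_or_chi2(tab[:, keep], max_exact_k) if keep.sum() >= 2 else np.nan
            labels_txt = _bin_labels(bins[colname])
            for j, txt in enumerate(labels_txt):
                rows.append(
                    {
                        "feature": colname,
                        "statistic": f"{txt}, n",
                        "rd": str(int(tab[0, j])),
                        "not_rd": str(int(tab[1, j])),
                        "p_value": p_bins if j == 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["feature", "statistic", "rd", "not_rd", "p_value"])


def _fisher_or_chi2(table: np.ndarray, max_exact_k: int) -> float:
    t = np.asarray(table, dtype=int)
    k = t.shape[1]
    small = t.sum() <= 400
    if k <= max_exact_k:
        try:
            if k == 2 or small:
                return fisher_exact_2xk(t)
        except ValueError:
            pass
    logger.warning("falling back to chi-square for a 2 x %d table (counts too large)", k)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or min(t.sum(axis=1)) == 0:
        return np.nan
    return float(stats.chi2_contingency(t)[1])


def _bin_labels(edges: list[float]) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    for a, b in zip(edges[:-1], edges[1:]):
        labels.append(f"{a:g}–{b:g}")
    labels.append(f"≥{edges[-1]:g}")
    return labels
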