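"""Rapid-decline labeling of eGFR trajectories.

Each eGFR test date (an *indication point*) is classified as RD or not_RD.
RD means the LOWESS-smoothed eGFR is below 60 mL/min/1.73 m^2 **and** has
dropped by at least 5 mL/min/1.73 m^2 relative to the smoothed curve one
year earlier.  Smoothing damps visit-timing artefacts and measurement
fluctuation; the one-year reference is read off the smoothed curve by linear
interpolation, and dates with less than a year of history cannot be
classified as RD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "RdCriteria",
    "smooth_series",
    "reference_value",
    "classify_indications",
    "label_cohort",
]

REASON_INSUFFICIENT_LOOKBACK = "insufficient_lookback"
REASON_ABOVE_THRESHOLD = "above_threshold"
REASON_DROP_TOO_SMALL = "drop_too_small"
REASON_RD = "rd"


@dataclass(frozen=True)
class RdCriteria:
    """Thresholds and smoothing settings for the RD criterion.

    egfr_threshold : mL/min/1.73 m^2 below which kidney disease is indicated.
    drop_threshold : minimum decrease vs one year earlier, same units.
    lookback_days : the "one year earlier" horizon.
    lowess_fraction, lowess_iterations : LOWESS span and robustifying
        iterations used to smooth the trajectory before the criterion is
        applied.
    on_smoothed : evaluate the criterion on the smoothed values (default);
        set False to apply it to raw values.
    """

    egfr_threshold: float = 60.0
    drop_threshold: float = 5.0
    lookback_days: int = 365
    lowess_fraction: float = 0.5
    lowess_iterations: int = 3
    on_smoothed: bool = True

    def __post_init__(self) -> None:
        if self.egfr_threshold <= 0 or self.drop_threshold <= 0 or self.lookback_days <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.lowess_fraction <= 1.0:
            raise ValueError("lowess_fraction must lie in (0, 1]")


def smooth_series(
    days: np.ndarray,
    values: np.ndarray,
    fraction: float = 0.5,
    iterations: int = 3,
) -> np.ndarray:
    """LOWESS-smooth an eGFR series, evaluated at the observed days.

    Locally weighted linear regression with tricube weights and
    ``iterations`` robustifying passes.  Series with fewer than 3 points are
    returned unchanged (the local fit is degenerate there), as is any series
    lying exactly on a straight line.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return values.copy()
    # the local window must hold at least 2 points for a linear fit
    frac = max(fraction, 2.0 / values.size)
    out = lowess(values, days, frac=frac, it=iterations, return_sorted=False)
    return np.asarray(out, dtype=float)


def reference_value(
    days: np.ndarray,
    smoothed: np.ndarray,
    t: float,
    lookback_days: int = 365,
) -> float | None:
    """Smoothed eGFR one lookback before day ``t``, or None.

    The smoothed curve is linearly interpolated at ``t - lookback_days``
    between the two bracketing observed days.  When no observation exists at
    or before that day the reference is undefined (None): the patient has
    insufficient history for the drop criterion.
    """
    days = np.asarray(days, dtype=float)
    t_ref = float(t) - lookback_days
    if days.size == 0 or t_ref < days[0]:
        return None
    return float(np.interp(t_ref, days, np.asarray(smoothed, dtype=float)))


def classify_indications(
    dates: pd.Series | np.ndarray,
    egfr: np.ndarray,
    criteria: RdCriteria = RdCriteria(),
) -> pd.DataFrame:
    """Classify every eGFR test date of one patient as RD or not_RD.

    Parameters
    ----------
    dates : strictly increasing test dates (datetime-like or day numbers).
    egfr : positive eGFR values, same length.
    criteria : thresholds and smoothing settings.

    Returns
    -------
    DataFrame with one row per test date: ``date``, ``egfr``, ``smoothed``,
    ``reference`` (NaN when undefined), ``rd_flag`` and ``reason`` (one of
    ``insufficient_lookback``, ``above_threshold``, ``drop_too_small``,
    ``rd``).  Every test date is classified; no minimum number of tests is
    required.
    """
    dates = pd.Series(dates).reset_index(drop=True)
    values = np.asarray(egfr, dtype=float)
    if len(dates) != values.size:
        raise ValueError("dates and egfr must have equal length")
    if values.size and np.any(values <= 0):
        raise ValueError("egfr values must be positive")
    if pd.api.types.is_datetime64_any_dtype(dates):
        days = (dates - dates.iloc[0]).dt.days.to_numpy(dtype=float) if len(dates) else np.array([])
    else:
        days = dates.to_numpy(dtype=float)
    if days.size > 1 and np.any(np.diff(days) <= 0):
        raise ValueError("dates must be strictly increasing")

    smoothed = smooth_series(days, values, criteria.lowess_fraction, criteria.lowess_iterations)
    basis = smoothed if criteria.on_smoothed else values

    rows = []
    for i in range(values.size):
        ref = reference_value(days, basis, days[i], criteria.lookback_days)
        if ref is None:
            flag, reason = False, REASON_INSUFFICIENT_LOOKBACK
        elif basis[i] >= criteria.egfr_threshold:
            flag, reason = False, REASON_ABOVE_THRESHOLD
        elif ref - basis[i] < criteria.drop_threshold:
            flag, reason = False, REASON_DROP_TOO_SMALL
        else:
            flag, reason = True, REASON_RD
        rows.append(
            {
                "date": dates.iloc[i],
                "egfr": values[i],
                "smoothed": smoothed[i] if values.size else np.nan,
                "reference": np.nan if ref is None else ref,
                "rd_flag": flag,
                "reason": reason,
            }
        )
    out = pd.DataFrame(
        rows, columns=["date", "egfr", "smoothed", "reference", "rd_flag", "reason"]
    )
    return out


def label_cohort(
    labs: pd.DataFrame,
    criteria: RdCriteria = RdCriteria(),
    egfr_code: str = "eGFR",
) -> pd.DataFrame:
    """Classify all patients' eGFR test dates from a long-format lab table.

    Returns the concatenated per-patient indication tables with a
    ``patient_id`` column prepended.
    """
    frames = []
    sub = labs[labs["test_code"] == egfr_code]
    for pid, grp in sub.groupby("patient_id", sort=True):
        grp = grp.sort_values("date", kind="stable")
        res = classify_indications(grp["date"], grp["value"].to_numpy(), criteria)
        res.insert(0, "patient_id", pid)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "date", "egfr", "smoothed", "reference", "rd_flag", "reason"]
        )
    return pd.concat(frames, ignore_index=True)
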