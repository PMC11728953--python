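"""Decision-point cohort construction.

A *decision point* is an eGFR test date at which the model is asked whether
an RD indication will occur within the following year (the event window).
Candidate dates are every eGFR test date inside the admissible decision
period; a candidate is excluded when the patient had dialysis or a kidney
transplant strictly before the date, when the date falls on or after the
patient's first RD indication (prediction stops once RD is indicated), or
when no other eGFR test exists within the year after (the label would be
unverifiable).  Multiple decision points per patient are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StudyWindows", "extract_decision_points"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyWindows:
    """Temporal geometry of the prediction task.

    input_window_days : feature lookback before a decision point; 54 weeks.
    event_window_days : label horizon after a decision point; 1 year.
    decision_start, decision_end : first/last admissible decision dates.
        ``decision_end`` should leave a full event window before the end of
        observation.
    """

    input_window_days: int = 378
    event_window_days: int = 365
    decision_start: pd.Timestamp | None = None
    decision_end: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.input_window_days <= 0 or self.event_window_days <= 0:
            raise ValueError("windows must be positive")


def extract_decision_points(
    patients: pd.DataFrame,
    indications: pd.DataFrame,
    windows: StudyWindows = StudyWindows(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select eligible decision points and label them.

    Parameters
    ----------
    patients : table with patient_id, dialysis_date, transplant_date
        (NaT when the event never happened).
    indications : per-test-date RD classification as produced by
        :func:`rdpredict.labeling.label_cohort` (columns patient_id, date,
        rd_flag).  Its dates double as the eGFR test dates.
    windows : study windows; when ``decision_start``/``decision_end`` are
        None the candidate range is unrestricted.

    Returns
    -------
    (decision_points, exclusion_counts) : eligible decision points with
    columns patient_id, date, label (True = RD within the event window) and
    the per-rule exclusion tally (candidates, excluded_censored,
    excluded_post_indication, excluded_no_followup, kept).
    """
    required = {"patient_id", "date", "rd_flag"}
    if missing := required - set(indications.columns):
        raise ValueError(f"indications table lacks columns: {sorted(missing)}")
    known = set(patients["patient_id"])
    unknown = set(indications["patient_id"]) - known
    if unknown:
        raise KeyError(f"patients absent from patient table: {sorted(unknown)[:5]}")

    censor = patients.set_index("patient_id")[["dialysis_date", "transplant_date"]]
    counts = {
        "candidates": 0,
        "excluded_censored": 0,
        "excluded_post_indication": 0,
        "excluded_no_followup": 0,
        "kept": 0,
    }
    horizon = pd.Timedelta(days=windows.event_window_days)
    rows = []
    for pid, grp in indications.groupby("patient_id", sort=True):
        grp = grp.sort_values("date", kind="stable")
        dates = pd.to_datetime(grp["date"]).reset_index(drop=True)
        flags = grp["rd_flag"].to_numpy(dtype=bool)
        rd_dates = dates[flags]
        first_rd = rd_dates.iloc[0] if len(rd_dates) else None
        dial = censor.at[pid, "dialysis_date"]
        tx = censor.at[pid, "transplant_date"]

        for i, t in enumerate(dates):
            if windows.decision_start is not None and t < windows.decision_start:
                continue
            if windows.decision_end is not None and t > windows.decision_end:
                continue
            counts["candidates"] += 1
            if (pd.notna(dial) and dial < t) or (pd.notna(tx) and tx < t):
                counts["excluded_censored"] += 1
                continue
            if first_rd is not None and t >= first_rd:
                counts["excluded_post_indication"] += 1
                continue
            later = dates[(dates > t) & (dates <= t + horizon)]
            if later.empty:
                counts["excluded_no_followup"] += 1
                continue
            label = bool(((rd_dates > t) & (rd_dates <= t + horizon)).any())
            counts["kept"] += 1
            rows.append({"patient_id": pid, "date": t, "label": label})

    logger.info("decision-point extraction: %s", counts)
    out = pd.DataFrame(rows, columns=["patient_id", "date", "label"])
    return out, counts
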