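"""Temporal "space" feature engineering for decision points.

For each decision point and each lab test code, observations inside the
54-week input window are nearest-neighbour interpolated to daily values
(no extrapolation beyond the observed span), the 378 days are partitioned
into 27 two-week *spaces*, and each space is represented by the natural log
of its mean daily value.  The most recent two weeks are the "1st space";
columns are named ``1st_space_of_<code>`` … ``27th_space_of_<code>``.
Missingness is preserved as NaN — the downstream learner routes missing
values natively.

Day offsets are ``d = decision_date - observation_date`` in days; the
decision date itself is ``d = 0`` and belongs to the 1st space.  Equidistant
nearest-neighbour ties resolve toward the more recent observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpaceGrid",
    "ordinal",
    "interpolate_daily",
    "quantize_spaces",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class SpaceGrid:
    """Partition of the input window into equal 2-week bins ("spaces").

    Space ``k`` (1-indexed) covers day offsets ``[14*(k-1), 14*k - 1]``;
    with the defaults the 27 spaces exactly tile the 378-day (54-week)
    input window.
    """

    n_spaces: int = 27
    space_width: int = 14

    def __post_init__(self) -> None:
        if self.n_spaces <= 0 or self.space_width <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def window_days(self) -> int:
        return self.n_spaces * self.space_width


def ordinal(k: int) -> str:
    """English ordinal string: 1 -> '1st', 2 -> '2nd', 11 -> '11th', ..."""
    if 10 <= k % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(k % 10, "th")
    return f"{k}{suffix}"


def feature_name(space: int, code: str) -> str:
    return f"{ordinal(space)}_space_of_{code}"


def interpolate_daily(
    offsets: np.ndarray,
    values: np.ndarray,
    grid: SpaceGrid = SpaceGrid(),
) -> np.ndarray:
    """Nearest-neighbour daily interpolation over the input window.

    ``offsets`` are day offsets ``d`` (0 = decision date) of the
    observations of one test, sorted ascending; only offsets inside
    ``[0, window_days)`` are used.  Days between the smallest and largest
    observed offset take the value of the nearest observation (ties to the
    smaller offset, i.e. the more recent observation); days outside that
    span are NaN — no extrapolation.
    """
    d = np.asarray(offsets, dtype=int)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise ValueError("offsets and values must have equal length")
    if d.size > 1 and np.any(np.diff(d) < 0):
        raise ValueError("offsets must be sorted ascending")
    n_days = grid.window_days
    out = np.full(n_days, np.nan)
    inside = (d >= 0) & (d < n_days)
    d, v = d[inside], v[inside]
    if d.size == 0:
        return out
    days = np.arange(d[0], d[-1] + 1)
    idx = np.searchsorted(d, days)
    idx = np.clip(idx, 1, d.size - 1) if d.size > 1 else np.zeros(days.size, dtype=int)
    if d.size > 1:
        left, right = d[idx - 1], d[idx]
        # tie (equidistant) resolves to the smaller offset = more recent obs
        take_left = (days - left) <= (right - days)
        nearest = np.where(take_left, idx - 1, idx)
    else:
        nearest = idx
    out[days] = v[nearest]
    return out


def quantize_spaces(daily: np.ndarray, grid: SpaceGrid = SpaceGrid()) -> np.ndarray:
    """Log-of-mean representative value per space.

    For each space, the mean of the non-missing daily values is taken and
    its natural log returned; a space with no data, or a non-positive mean,
    is NaN.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.size != grid.window_days:
        raise ValueError(f"expected a daily array of length {grid.window_days}")
    seg = daily.reshape(grid.n_spaces, grid.space_width)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(seg), axis=1)
        means = np.where(counts > 0, np.nansum(seg, axis=1) / np.maximum(counts, 1), np.nan)
        out = np.where((counts > 0) & (means > 0), np.log(np.where(means > 0, means, 1.0)), np.nan)
    return out


def features_for_decision_point(
    offsets: np.ndarray,
    values: np.ndarray,
    grid: SpaceGrid = SpaceGrid(),
) -> np.ndarray:
    """Reference route: interpolate daily, then quantize into spaces."""
    return quantize_spaces(interpolate_daily(offsets, values, grid), grid)


def build_feature_matrix(
    decision_points: pd.DataFrame,
    labs: pd.DataFrame,
    test_codes: list[str],
    grid: SpaceGrid = SpaceGrid(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Tabulate decision points into the space-feature matrix.

    Parameters
    ----------
    decision_points : table with patient_id, date and (optionally) label.
    labs : long-format observations (patient_id, date, test_code, value).
    test_codes : the codes to featurize, in the desired column-block order;
        a code never observed anywhere in ``labs`` is an error (it is
        presumed a configuration typo).
    grid : the space grid.

    Returns
    -------
    (X, y) : ``X`` has one row per decision point and
    ``grid.n_spaces * len(test_codes)`` columns named
    ``{ordinal}_space_of_{code}``; ``y`` is the label vector (all-False when
    the decision table has no label column).

    Notes
    -----
    Internally uses a prefix-sum shortcut equivalent to
    :func:`interpolate_daily` + :func:`quantize_spaces` applied per decision
    point: nearest-neighbour values are constant on day runs between
    observations, so per-space means can be read from cumulative sums of the
    patient-level daily interpolation restricted to the window.
    """
    observed = set(labs["test_code"].unique())
    unknown = [c for c in test_codes if c not in observed]
    if unknown:
        raise ValueError(f"test codes absent from the lab table: {unknown}")

    columns = [feature_name(k, c) for c in test_codes for k in range(1, grid.n_spaces + 1)]
    n_dp = len(decision_points)
    X = np.full((n_dp, len(columns)), np.nan)

    dp = decision_points.reset_index(drop=True)
    dp_day_all = (pd.to_datetime(dp["date"]).astype("int64") // 86_400_000_000_000).to_numpy()
    labs = labs[labs["test_code"].isin(test_codes)]
    lab_day = (pd.to_datetime(labs["date"]).astype("int64") // 86_400_000_000_000).to_numpy()

    code_pos = {c: i for i, c in enumerate(test_codes)}
    dp_rows_by_pid = {pid: idx.to_numpy() for pid, idx in dp.groupby("patient_id").groups.items()}
    W = grid.window_days
    ns, sw = grid.n_spaces, grid.space_width

    # flatten the (patient, code) grouping to sorted integer keys so each
    # series is a contiguous numpy slice — pandas groupby is too slow here
    pid_codes, pid_idx = np.unique(labs["patient_id"].to_numpy(), return_inverse=True)
    code_idx = np.fromiter(
        (code_pos[c] for c in labs["test_code"].to_numpy()), dtype=np.int64, count=len(labs)
    )
    key = pid_idx * len(test_codes) + code_idx
    order = np.lexsort((lab_day, key))
    key_s, day_s = key[order], lab_day[order]
    val_s = labs["value"].to_numpy(dtype=float)[order]
    bounds = np.concatenate([[0], np.nonzero(np.diff(key_s))[0] + 1, [key_s.size]])

    for si in range(bounds.size - 1):
        a0, b0 = bounds[si], bounds[si + 1]
        if a0 == b0:
            continue
        pid = pid_codes[key_s[a0] // len(test_codes)]
        code = test_codes[key_s[a0] % len(test_codes)]
        rows = dp_rows_by_pid.get(pid)
        if rows is None:
            continue
        o = day_s[a0:b0]
        v = val_s[a0:b0]
        o, v = _dedupe_days(o, v)
        daily = _daily_nn(o, v)  # values for days o[0] .. o[-1]
        cs = np.concatenate([[0.0], np.cumsum(daily)])
        t = dp_day_all[rows]  # decision days, shape (m,)

        lo_idx = np.searchsorted(o, t - (W - 1), side="left")
        hi_idx = np.searchsorted(o, t, side="right") - 1
        valid = hi_idx >= lo_idx
        if not valid.any():
            continue
        lo = np.where(valid, o[np.clip(lo_idx, 0, o.size - 1)], 0)
        hi = np.where(valid, o[np.clip(hi_idx, 0, o.size - 1)], -1)

        k = np.arange(1, ns + 1)
        # space k covers absolute days [t - k*sw + 1, t - (k-1)*sw]
        a = np.maximum(t[:, None] - k[None, :] * sw + 1, lo[:, None])
        b = np.minimum(t[:, None] - (k[None, :] - 1) * sw, hi[:, None])
        ok = (b >= a) & valid[:, None]
        ai = np.clip(a - o[0], 0, daily.size)
        bi = np.clip(b - o[0] + 1, 0, daily.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(ok, (cs[bi] - cs[ai]) / np.maximum(b - a + 1, 1), np.nan)
            vals = np.where(ok & (means > 0), np.log(np.where(means > 0, means, 1.0)), np.nan)
        c0 = code_pos[code] * ns
        X[np.asarray(rows)[:, None], np.arange(c0, c0 + ns)[None, :]] = vals

    Xdf = pd.DataFrame(X, columns=columns, index=dp.index)
    y = (
        dp["label"].astype(bool)
        if "label" in dp.columns
        else pd.Series(False, index=dp.index, name="label")
    )
    return Xdf, y.rename("label")


def _dedupe_days(o: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average same-day repeat measurements so days are strictly increasing."""
    if o.size < 2 or np.all(np.diff(o) > 0):
        return o, v
    uo, inv = np.unique(o, return_inverse=True)
    sums = np.bincount(inv, weights=v)
    cnts = np.bincount(inv)
    return uo, sums / cnts


def _daily_nn(o: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Nearest-neighbour daily values over the full span of one series.

    Ties between two bracketing observations go to the later (more recent)
    one, matching the per-window tie rule: within any window the nearest
    in-window observation of an interior day equals the global nearest.
    """
    days = np.arange(o[0], o[-1] + 1)
    if o.size == 1:
        return v.copy()
    idx = np.clip(np.searchsorted(o, days), 1, o.size - 1)
    left, right = o[idx - 1], o[idx]
    take_right = (right - days) <= (days - left)
    nearest = np.where(take_right, idx, idx - 1)
    return v[nearest]
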