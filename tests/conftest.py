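import numpy as np
import pandas as pd
import pytest

import rdpredict as rp


@pytest.fixture(scope="session")
def small_cohort():
    """A compact deterministic synthetic cohort shared across tests."""
    cfg = rp.GeneratorConfig(
        n_patients=80, n_tests=6, informative_tests=("LAB003",), visit_rate=8.0, seed=11
    )
    patients, labs, gt = rp.generate_cohort(cfg)
    return cfg, patients, labs, gt


@pytest.fixture(scope="session")
def labeled_cohort(small_cohort):
    cfg, patients, labs, gt = small_cohort
    indications = rp.label_cohort(labs)
    windows = rp.StudyWindows(
        decision_end=pd.Timestamp(cfg.study_end) - pd.Timedelta(days=365)
    )
    dp, counts = rp.extract_decision_points(patients, indications, windows)
    return cfg, patients, labs, gt, indications, dp


def make_piecewise_series(rng, n_points=30, span_days=1100):
    """Random noise-free piecewise-linear eGFR series plus its closed form.

    Returns (days, values, f) where f(day) evaluates the exact line.
    """
    days = np.sort(rng.choice(np.arange(span_days), size=n_points, replace=False))
    baseline = rng.uniform(50.0, 90.0)
    slope1 = rng.uniform(-6.0, 1.0) / 365.0
    slope2 = rng.uniform(-15.0, -2.0) / 365.0
    knee = rng.uniform(200, span_days - 200)

    def f(d):
        d = np.asarray(d, dtype=float)
        before = baseline + slope1 * d
        after = baseline + slope1 * knee + slope2 * (d - knee)
        return np.maximum(np.where(d <= knee, before, after), 1.0)

    return days.astype(float), f(days), f


def criterion_oracle(days, values, egfr_threshold=60.0, drop_threshold=5.0, lookback=365):
    """Direct, independent evaluation of the RD drop criterion.

    For each test day t: the reference is the linear interpolation of the
    observed (day, value) pairs at t - lookback, undefined when t - lookback
    precedes the first observation; RD iff value(t) < egfr_threshold and
    reference - value(t) >= drop_threshold.
    """
    flags = []
    for i, t in enumerate(days):
        t_ref = t - lookback
        if t_ref < days[0]:
            flags.append(False)
            continue
        ref = float(np.interp(t_ref, days, values))
        flags.append(values[i] < egfr_threshold and ref - values[i] >= drop_threshold)
    return np.array(flags, dtype=bool)
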