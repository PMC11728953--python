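"""Space features: daily interpolation, 2-week quantization, matrix build."""

import numpy as np
import pandas as pd
import pytest

import rdpredict as rp
from rdpredict.features import feature_name, features_for_decision_point, ordinal

START = pd.Timestamp("2020-06-01")


def make_labs(pid_days_vals, code="eGFR"):
    rows = []
    for pid, day, val in pid_days_vals:
        rows.append({"patient_id": pid, "date": START + pd.Timedelta(days=day), "test_code": code, "value": val})
    return pd.DataFrame(rows)


class TestInterpolateDaily:
    def test_three_observation_example(self):
        # observations 1, 29 and 64 days before the decision point: days
        # 2-28 and 30-63 are filled by the nearest neighbour, day 0 and
        # days >= 65 stay missing
        daily = rp.interpolate_daily(np.array([1, 29, 64]), np.array([10.0, 20.0, 30.0]))
        assert np.isnan(daily[0])
        assert not np.isnan(daily[1:65]).any()
        assert np.isnan(daily[65:]).all()
        assert daily[1] == 10 and daily[29] == 20 and daily[64] == 30
        assert daily[14] == 10  # |14-1| = 13 < |29-14| = 15
        assert daily[15] == 10  # equidistant tie -> more recent observation
        assert daily[16] == 20

    def test_single_observation_no_extrapolation(self):
        daily = rp.interpolate_daily(np.array([10]), np.array([7.0]))
        assert daily[10] == 7.0
        mask = np.ones(daily.size, dtype=bool)
        mask[10] = False
        assert np.isnan(daily[mask]).all()

    def test_tie_resolves_to_more_recent(self):
        # a at d=10, b at d=20: days 10-14 -> a, day 15 equidistant -> a
        # (smaller offset = more recent), days 16-20 -> b
        daily = rp.interpolate_daily(np.array([10, 20]), np.array([1.0, 2.0]))
        assert np.all(daily[10:16] == 1.0)
        assert np.all(daily[16:21] == 2.0)

    def test_no_observations_all_missing(self):
        daily = rp.interpolate_daily(np.array([], dtype=int), np.array([]))
        assert daily.shape == (378,) and np.isnan(daily).all()

    def test_out_of_window_offsets_ignored(self):
        daily = rp.interpolate_daily(np.array([-5, 100, 400]), np.array([1.0, 2.0, 3.0]))
        assert daily[100] == 2.0
        assert np.isnan(np.delete(daily, 100)).all()


class TestQuantizeSpaces:
    def test_constant_input_gives_log_everywhere(self):
        out = rp.quantize_spaces(np.full(378, 5.0))
        assert out.shape == (27,)
        assert np.allclose(out, np.log(5.0))

    def test_mean_then_log(self):
        daily = np.full(378, np.nan)
        daily[0], daily[1] = np.e**2, np.e**4
        out = rp.quantize_spaces(daily)
        assert out[0] == pytest.approx(np.log((np.e**2 + np.e**4) / 2), abs=1e-6)
        assert out[0] == pytest.approx(3.43378, abs=1e-4)
        assert np.isnan(out[1:]).all()

    def test_empty_space_and_nonpositive_mean_missing(self):
        daily = np.full(378, np.nan)
        daily[20] = -1.0  # space 2 has a non-positive mean
        out = rp.quantize_spaces(daily)
        assert np.isnan(out).all()

    def test_partition_covers_every_day_once(self):
        grid = rp.SpaceGrid()
        assert grid.n_spaces * grid.space_width == 378
        space_of_day = np.repeat(np.arange(1, 28), 14)
        assert space_of_day.size == 378
        # day 13 is the last day of space 1; day 14 the first of space 2
        assert space_of_day[13] == 1 and space_of_day[14] == 2


class TestOrdinalNames:
    @pytest.mark.parametrize(
        "k,name", [(1, "1st"), (2, "2nd"), (3, "3rd"), (4, "4th"), (11, "11th"), (21, "21st"), (27, "27th")]
    )
    def test_ordinals(self, k, name):
        assert ordinal(k) == name

    def test_feature_name_layout(self):
        assert feature_name(1, "eGFR") == "1st_space_of_eGFR"
        assert feature_name(27, "HbA1c") == "27th_space_of_HbA1c"


class TestBuildMatrix:
    def dp(self, days, pid="P1"):
        return pd.DataFrame(
            {"patient_id": pid, "date": [START + pd.Timedelta(days=d) for d in days], "label": False}
        )

    def test_one_code_27_columns(self):
        labs = make_labs([("P1", 0, 50.0), ("P1", 5, 55.0)])
        X, y = rp.build_feature_matrix(self.dp([10]), labs, ["eGFR"])
        assert X.shape == (1, 27)
        assert list(X.columns)[0] == "1st_space_of_eGFR"

    def test_unknown_code_is_hard_error(self):
        labs = make_labs([("P1", 0, 50.0)])
        with pytest.raises(ValueError):
            rp.build_feature_matrix(self.dp([10]), labs, ["eGFR", "NOPE"])

    def test_leakage_guard_outside_window(self):
        labs = make_labs([("P1", 100, 50.0), ("P1", 130, 60.0)])
        dp = self.dp([400])  # observation at d=300 and 270
        X1, _ = rp.build_feature_matrix(dp, labs, ["eGFR"])
        labs2 = pd.concat(
            [labs, make_labs([("P1", 900, 999.0), ("P1", 10, 777.0)])], ignore_index=True
        )  # d = -500 (future) and d = 390 (too old): both outside the window
        X2, _ = rp.build_feature_matrix(dp, labs2, ["eGFR"])
        pd.testing.assert_frame_equal(X1, X2)

    def test_step_change_moves_between_first_and_second_space(self):
        # value step planted at the d=13/14 boundary must switch columns
        labs_recent = make_labs([("P1", 400 - 13, np.e), ("P1", 0, 1.0)])
        labs_older = make_labs([("P1", 400 - 14, np.e), ("P1", 0, 1.0)])
        X_recent, _ = rp.build_feature_matrix(self.dp([400]), labs_recent, ["eGFR"])
        X_older, _ = rp.build_feature_matrix(self.dp([400]), labs_older, ["eGFR"])
        assert X_recent.iloc[0]["1st_space_of_eGFR"] == pytest.approx(1.0)
        assert np.isnan(X_older.iloc[0]["1st_space_of_eGFR"])
        assert X_older.iloc[0]["2nd_space_of_eGFR"] == pytest.approx(1.0)

    def test_decision_day_itself_belongs_to_first_space(self):
        labs = make_labs([("P1", 50, np.e**3)])
        X, _ = rp.build_feature_matrix(self.dp([50]), labs, ["eGFR"])
        assert X.iloc[0]["1st_space_of_eGFR"] == pytest.approx(3.0)
        assert np.isnan(X.iloc[0]["2nd_space_of_eGFR"])

    @pytest.mark.parametrize("seed", range(8))
    def test_fast_path_matches_reference_route(self, seed):
        """The prefix-sum matrix builder must agree exactly with the
        interpolate-then-quantize reference on random irregular series."""
        rng = np.random.default_rng(seed)
        n_obs = rng.integers(1, 25)
        obs_days = np.sort(rng.choice(np.arange(0, 700), size=n_obs, replace=False))
        vals = rng.uniform(0.5, 120.0, size=n_obs)
        t = int(rng.integers(300, 650))
        labs = make_labs([("P1", int(d), float(v)) for d, v in zip(obs_days, vals)])
        X, _ = rp.build_feature_matrix(self.dp([t]), labs, ["eGFR"])
        d_off = t - obs_days[::-1]
        ref = features_for_decision_point(d_off, vals[::-1])
        np.testing.assert_allclose(X.iloc[0].to_numpy(), ref, rtol=1e-9, equal_nan=True)

    def test_multi_patient_rows_align(self, labeled_cohort):
        cfg, patients, labs, gt, indications, dp = labeled_cohort
        codes = sorted(labs["test_code"].unique())
        X, y = rp.build_feature_matrix(dp, labs, codes)
        assert X.shape == (len(dp), 27 * len(codes))
        assert y.to_numpy().sum() == dp["label"].sum()
        # the decision date is an eGFR test date, so the 1st eGFR space of
        # every row is populated whenever that eGFR row survived missingness
        egfr_cols = [c for c in X.columns if c.endswith("_of_eGFR")]
        assert X[egfr_cols].notna().any(axis=1).mean() > 0.9
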