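"""Feature extraction, selection and scaling against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import vo2arm as v
from vo2arm.features import (
    STAT_NAMES,
    columns_for_combo,
    feature_names,
    split_feature_columns,
)

#: the 69 feature names reported as selected for the deployed armband model
PUBLISHED_SELECTED = [
    "Acc_mean", "EMGsum_lag1", "Gyro_mean", "az_per50", "az_median", "az_avg",
    "az_per25", "az_sum", "az_per75", "az_per10", "az_per90", "az_per95",
    "az_per5", "az_max", "ax_max", "gz_stdev", "ax_per95", "gz_min", "gz_max",
    "ax_stdev", "gz_per95", "ax_per90", "ay_stdev", "gz_per5", "az_min",
    "gz_per90", "gz_var", "gx_stdev", "gz_per10", "gx_max", "ax_per75",
    "gx_min", "gy_stdev", "res_gyro_max", "gy_max", "ay_var", "res_acc_skew",
    "res_gyro_per95", "gy_min", "res_gyro_avg", "res_gyro_sum", "ay_min",
    "ax_sum", "ax_var", "gx_var", "res_gyro_median", "res_gyro_per50",
    "res_gyro_stdev", "res_gyro_per90", "gx_per5", "gy_per95", "gz_per75",
    "az_skew", "EMG7_per25", "ax_skew", "res_acc_max", "res_gyro_per75",
    "gy_per5", "gx_per95", "ax_avg", "res_acc_per95", "ax_median", "ax_per50",
    "EMG8_per25", "EMG8_per75", "gy_per10", "EMGsum_var", "res_gyro_per25",
    "gy_per90",
]


def brute_force_stats(seq):
    """Independent oracle: direct moment sums and sorting-based percentiles."""
    x = sorted(float(s) for s in seq)
    n = len(x)
    mean = sum(x) / n
    var = sum((xi - mean) ** 2 for xi in x) / n
    std = var**0.5
    m3 = sum((xi - mean) ** 3 for xi in x) / n
    m4 = sum((xi - mean) ** 4 for xi in x) / n

    def percentile(q):
        pos = q / 100 * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    return {
        "sum": sum(x), "avg": mean, "min": x[0], "max": x[-1],
        "median": percentile(50), "stdev": std,
        "cv": std / mean if mean != 0 else 0.0, "var": var,
        "per5": percentile(5), "per10": percentile(10), "per25": percentile(25),
        "per50": percentile(50), "per75": percentile(75), "per90": percentile(90),
        "per95": percentile(95),
        "skew": m3 / var**1.5 if var > 0 else 0.0,
        "kurtosis": m4 / var**2 - 3 if var > 0 else 0.0,
    }


class TestResultants:
    def test_definitions(self):
        accel = np.array([[0.0, 0, 0], [3, 4, 0]])
        gyro = np.array([[1.0, 2, 2], [0, 0, 0]])
        emg = np.zeros((2, 8))
        emg[0, :2] = [-10, 10]
        res = v.compute_resultants(accel, gyro, emg)
        np.testing.assert_allclose(res["res_acc"], [0.0, 5.0])
        np.testing.assert_allclose(res["res_gyro"], [3.0, 0.0])
        np.testing.assert_allclose(res["EMGsum"], [20.0, 0.0])


class TestWindowStats:
    def test_constant_sequence_conventions(self):
        out = v.window_stats([4.0] * 10)
        assert out["sum"] == 40 and out["avg"] == 4
        assert out["stdev"] == out["var"] == out["cv"] == 0
        assert out["skew"] == out["kurtosis"] == 0
        for q in ("per5", "per25", "per50", "per75", "per95", "median"):
            assert out[q] == 4

    def test_hand_computed_example(self):
        out = v.window_stats([1, 2, 3, 4])
        assert out["sum"] == 10 and out["avg"] == 2.5 and out["median"] == 2.5
        assert out["var"] == pytest.approx(1.25)
        assert out["stdev"] == pytest.approx(1.25**0.5)
        assert out["cv"] == pytest.approx(1.25**0.5 / 2.5)

    def test_interpolated_percentile(self):
        assert v.window_stats([0, 10])["per25"] == pytest.approx(2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            v.window_stats([])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = rng.normal(size=rng.integers(3, 200))
        ours = v.window_stats(seq)
        oracle = brute_force_stats(seq)
        for name in STAT_NAMES:
            assert ours[name] == pytest.approx(oracle[name], abs=1e-9), name


class TestFeatureTable:
    def test_default_mode_has_290_columns(self, tiny_cohort):
        table = v.build_feature_table(tiny_cohort[0])
        cols = split_feature_columns(table)
        assert len(cols) == 290
        stat_cols = [c for c in cols if c != "EMGsum_lag1"]
        assert len(stat_cols) == 289 == 17 * 17

    def test_extended_mode_has_295_columns(self, tiny_cohort):
        table = v.build_feature_table(
            tiny_cohort[0], v.FeatureSpec(derived_mode="extended_295")
        )
        assert len(split_feature_columns(table)) == 295

    def test_published_selected_names_are_producible(self):
        producible = set(feature_names("extended_295"))
        missing = [n for n in PUBLISHED_SELECTED if n not in producible]
        assert missing == []

    def test_lag_drops_first_row(self, tiny_script):
        cohort = v.generate_cohort(2, script_template=tiny_script, seed=0)
        rec = cohort[0]
        table = v.build_feature_table(rec)
        assert len(table) == rec.vo2.n_samples - 1

    def test_lag_feature_is_previous_seconds_mean(self, tiny_cohort):
        table = v.build_feature_table(tiny_cohort[0])
        np.testing.assert_allclose(
            table["EMGsum_lag1"].to_numpy()[1:],
            table["EMGsum_avg"].to_numpy()[:-1],
        )

    def test_short_recording_rejected(self, tiny_cohort):
        rec = tiny_cohort[0]
        import dataclasses

        from vo2arm.signal_io import ChannelStream

        short = dataclasses.replace(
            rec,
            emg=ChannelStream("emg", 200, 0, rec.emg.values[:400]),
            accel=ChannelStream("accel", 50, 0, rec.accel.values[:100]),
            gyro=ChannelStream("gyro", 50, 0, rec.gyro.values[:100]),
            vo2=ChannelStream("vo2", 1, 0, rec.vo2.values[:2]),
            labels=None,
            vo2_truth=None,
        )
        with pytest.raises(ValueError, match="3"):
            v.build_feature_table(short)

    def test_sensor_combo_filters(self):
        cols = feature_names("extended_295")
        emg_cols = columns_for_combo(cols, "emg")
        imu_cols = columns_for_combo(cols, "imu")
        assert all(c.startswith("EMG") for c in emg_cols)
        assert "EMGsum_lag1" in emg_cols and "EMGsum_var" in emg_cols
        assert "Acc_mean" in imu_cols and "res_gyro_max" in imu_cols
        assert set(emg_cols) | set(imu_cols) == set(cols)
        assert not set(emg_cols) & set(imu_cols)


class TestSelection:
    def _table(self, features: dict, target) -> pd.DataFrame:
        df = pd.DataFrame(features)
        df["target"] = target
        df["subject_id"] = "s"
        return df

    def test_identical_feature_kept_with_r_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=200)
        res = v.select_features(self._table({"f": y}, y))
        assert res.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert bool(res.loc[0, "kept"])

    def test_mi_invariant_under_negation(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=300)
        res = v.select_features(self._table({"pos": y, "neg": -y}, y))
        r = res.set_index("feature")
        assert abs(r.loc["neg", "pearson_r"]) == pytest.approx(1.0)
        assert r.loc["neg", "mutual_info"] == pytest.approx(
            r.loc["pos", "mutual_info"], rel=1e-6
        )

    def test_independent_noise_dropped_at_large_n(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=5000)
        noise = rng.normal(size=5000)
        res = v.select_features(self._table({"noise": noise}, y))
        assert not bool(res.loc[0, "kept"])

    def test_zero_variance_feature_never_kept(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        res = v.select_features(self._table({"const": np.ones(50)}, y))
        assert res.loc[0, "pearson_r"] == 0.0
        assert not bool(res.loc[0, "kept"])

    def test_selection_monotone_in_thresholds(self, tiny_table):
        cols = split_feature_columns(tiny_table)[:40]
        sub = tiny_table[cols + ["target", "subject_id"]]
        kept = {}
        for thr in (0.05, 0.2, 0.5):
            res = v.select_features(sub, r_threshold=thr, mi_threshold=thr)
            kept[thr] = set(res.loc[res["kept"], "feature"])
        assert kept[0.5] <= kept[0.2] <= kept[0.05]

    def test_too_few_rows_rejected(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            v.select_features(self._table({"f": y}, y))


class TestScaler:
    def _table(self, col):
        df = pd.DataFrame({"f": col})
        df["target"] = np.arange(len(col), dtype=float)
        df["subject_id"] = "s"
        return df

    def test_affine_map_endpoints(self):
        t = self._table([0.0, 5.0, 10.0])
        scaler = v.fit_scaler(t)
        out = v.apply_scaler(scaler, t)
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        t = self._table([7.0, 7.0, 7.0])
        out = v.apply_scaler(v.fit_scaler(t), t)
        np.testing.assert_allclose(out["f"], 0.0)

    def test_out_of_range_values_not_clipped(self):
        fit_t = self._table([0.0, 10.0])
        scaler = v.fit_scaler(fit_t)
        test_t = self._table([12.0, -2.0])
        out = v.apply_scaler(scaler, test_t)
        np.testing.assert_allclose(out["f"], [1.2, -0.2])
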