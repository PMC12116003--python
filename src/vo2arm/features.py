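"""Per-second feature engineering, selection, and scaling.

Raw 200 Hz EMG and 50 Hz IMU streams are reduced to one feature row per
whole second (non-overlapping windows), aligned with the 1 Hz VO2 target:

* 17 raw channels — ax, ay, az, res_acc, gx, gy, gz, res_gyro, EMG1..EMG8,
  EMGsum — where res_acc/res_gyro are per-sample Euclidean resultants and
  EMGsum is the per-sample sum of absolute channel values (signed 8-bit EMG
  would cancel to ~0 under a raw sum);
* 17 window statistics per channel — sum, avg, min, max, median, stdev, cv,
  var, percentiles 5/10/25/50/75/90/95, skew, kurtosis — giving 289
  statistical columns named ``<channel>_<stat>``;
* derived history columns: the default ``basic_290`` mode appends one lag
  feature (``EMGsum_lag1``, the previous second's EMGsum mean) for 290
  columns total; ``extended_295`` additionally shifts and rolling-averages
  (window 3) the second-level means of res_acc, res_gyro and EMGsum
  (``Acc_lag1``, ``Acc_mean``, ...), for 295.

Features are kept when both |Pearson r| and mutual information against the
target exceed their thresholds (default 0.1 each), then min-max scaled to
[0, 1] on the fitting partition only (test-fold values are not clipped).

Conventions, stated so oracles can match exactly: population (ddof=0)
variance and stdev; cv = stdev/avg with 0 when avg = 0; linear-interpolation
percentiles; population Fisher skew and excess kurtosis, both 0 for
zero-variance windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import mutual_info_regression
from sklearn.preprocessing import MinMaxScaler

from .signal_io import SensorRecording

__all__ = [
    "STAT_NAMES",
    "CHANNEL_NAMES",
    "FeatureSpec",
    "compute_resultants",
    "window_stats",
    "build_feature_table",
    "CorrMISelector",
    "select_features",
    "fit_scaler",
    "apply_scaler",
    "feature_names",
    "columns_for_combo",
]

STAT_NAMES = [
    "sum", "avg", "min", "max", "median", "stdev", "cv", "var",
    "per5", "per10", "per25", "per50", "per75", "per90", "per95",
    "skew", "kurtosis",
]

#: 17 raw channels in table order: accelerometer axes + resultant, gyro axes
#: + resultant, 8 EMG channels + their aggregate amplitude.
CHANNEL_NAMES = (
    ["ax", "ay", "az", "res_acc", "gx", "gy", "gz", "res_gyro"]
    + [f"EMG{i}" for i in range(1, 9)]
    + ["EMGsum"]
)

#: (lag/rolling base channel, display prefix) pairs for derived columns
_DERIVED_BASES = [("res_acc", "Acc"), ("res_gyro", "Gyro"), ("EMGsum", "EMGsum")]

_IMU_PREFIXES = ("ax_", "ay_", "az_", "res_acc_", "gx_", "gy_", "gz_", "res_gyro_",
                 "Acc_", "Gyro_")
_EMG_PREFIXES = tuple(f"EMG{i}_" for i in range(1, 9)) + ("EMGsum_",)


@dataclass
class FeatureSpec:
    """Which derived columns exist beyond the 289 statistical ones."""

    derived_mode: str = "basic_290"  # or "extended_295"
    stat_names: list[str] = field(default_factory=lambda: list(STAT_NAMES))
    raw_channels: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))

    def __post_init__(self) -> None:
        if self.derived_mode not in ("basic_290", "extended_295"):
            raise ValueError(f"unknown derived_mode {self.derived_mode!r}")

    @property
    def n_columns(self) -> int:
        return len(self.feature_names())

    def feature_names(self) -> list[str]:
        names = [f"{ch}_{st}" for ch in self.raw_channels for st in self.stat_names]
        if self.derived_mode == "basic_290":
            names.append("EMGsum_lag1")
        else:
            for _, prefix in _DERIVED_BASES:
                names.append(f"{prefix}_lag1")
            for _, prefix in _DERIVED_BASES:
                names.append(f"{prefix}_mean")
        return names


def feature_names(derived_mode: str = "basic_290") -> list[str]:
    return FeatureSpec(derived_mode=derived_mode).feature_names()


# ---------------------------------------------------------------------------
# Resultants and window statistics


def compute_resultants(
    accel: np.ndarray, gyro: np.ndarray, emg: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-sample resultant magnitudes and aggregate EMG amplitude.

    ``res_acc``/``res_gyro`` are Euclidean norms of the three axes per 50 Hz
    sample; ``EMGsum`` is the sum of absolute values over the 8 channels per
    200 Hz sample.
    """
    accel = np.asarray(accel, float)
    gyro = np.asarray(gyro, float)
    emg = np.asarray(emg, float)
    return {
        "res_acc": np.linalg.norm(accel, axis=1),
        "res_gyro": np.linalg.norm(gyro, axis=1),
        "EMGsum": np.sum(np.abs(emg), axis=1),
    }


def _stats_matrix(windows: np.ndarray) -> np.ndarray:
    """All 17 statistics for each row of ``windows`` (n_windows, width)."""
    w = np.asarray(windows, float)
    n = w.shape[1]
    mean = w.mean(axis=1)
    var = w.var(axis=1)  # population
    std = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, std / np.where(mean != 0.0, mean, 1.0), 0.0)
    centered = w - mean[:, None]
    m3 = np.mean(centered**3, axis=1)
    m4 = np.mean(centered**4, axis=1)
    nonzero = var > 0
    skew = np.zeros_like(mean)
    kurt = np.zeros_like(mean)
    skew[nonzero] = m3[nonzero] / var[nonzero] ** 1.5
    kurt[nonzero] = m4[nonzero] / var[nonzero] ** 2 - 3.0
    pers = np.percentile(w, [5, 10, 25, 50, 75, 90, 95], axis=1)  # linear interp
    cols = [
        w.sum(axis=1), mean, w.min(axis=1), w.max(axis=1), pers[3], std, cv, var,
        pers[0], pers[1], pers[2], pers[3], pers[4], pers[5], pers[6], skew, kurt,
    ]
    return np.column_stack(cols)


def window_stats(values) -> dict[str, float]:
    """The 17 named statistics of one window (sequence of length >= 1)."""
    arr = np.asarray(values, float).ravel()
    if arr.size == 0:
        raise ValueError("window_stats requires a non-empty sequence")
    row = _stats_matrix(arr[None, :])[0]
    return dict(zip(STAT_NAMES, row))


# ---------------------------------------------------------------------------
# Feature table


def build_feature_table(
    rec: SensorRecording, spec: FeatureSpec | None = None
) -> pd.DataFrame:
    """Per-second feature matrix aligned with the 1 Hz VO2 target.

    The recording must already be trimmed to whole seconds.  The first row is
    dropped (lag features undefined there), so an S-second recording yields
    S − 1 rows.  Output columns: features in spec order, then ``target``
    (observed VO2), ``target_truth`` when the recording carries noiseless
    ground truth, ``subject_id``, and ``activity`` when labels exist.
    """
    if spec is None:
        spec = FeatureSpec()
    n_sec = rec.vo2.n_samples
    if n_sec < 3:
        raise ValueError("recording must cover at least 3 whole seconds")
    imu_rate = int(round(rec.accel.rate))
    emg_rate = int(round(rec.emg.rate))
    if rec.accel.n_samples != n_sec * imu_rate or rec.emg.n_samples != n_sec * emg_rate:
        raise ValueError(
            "streams not trimmed to whole seconds; run trim_to_overlap first"
        )

    res = compute_resultants(rec.accel.values, rec.gyro.values, rec.emg.values)
    per_sample = {
        "ax": rec.accel.values[:, 0], "ay": rec.accel.values[:, 1],
        "az": rec.accel.values[:, 2], "res_acc": res["res_acc"],
        "gx": rec.gyro.values[:, 0], "gy": rec.gyro.values[:, 1],
        "gz": rec.gyro.values[:, 2], "res_gyro": res["res_gyro"],
        **{f"EMG{i}": rec.emg.values[:, i - 1].astype(float) for i in range(1, 9)},
        "EMGsum": res["EMGsum"],
    }
    data = {}
    for ch in spec.raw_channels:
        sig = np.asarray(per_sample[ch], float)
        rate = emg_rate if ch.startswith("EMG") else imu_rate
        stats = _stats_matrix(sig.reshape(n_sec, rate))
        for j, st in enumerate(spec.stat_names):
            data[f"{ch}_{st}"] = stats[:, j]
    df = pd.DataFrame(data)

    second_means = {prefix: df[f"{base}_avg"] for base, prefix in _DERIVED_BASES}
    if spec.derived_mode == "basic_290":
        df["EMGsum_lag1"] = second_means["EMGsum"].shift(1)
    else:
        for _, prefix in _DERIVED_BASES:
            df[f"{prefix}_lag1"] = second_means[prefix].shift(1)
        for _, prefix in _DERIVED_BASES:
            # rolling mean over the current and up to 2 preceding seconds
            df[f"{prefix}_mean"] = second_means[prefix].rolling(3, min_periods=1).mean()

    df["target"] = rec.vo2.values[:, 0]
    if rec.vo2_truth is not None:
        df["target_truth"] = np.asarray(rec.vo2_truth, float)
    df["subject_id"] = rec.subject_id
    if rec.labels is not None:
        df["activity"] = np.asarray(rec.labels, dtype=object)
    df = df.iloc[1:].reset_index(drop=True)  # lag row
    assert not df[spec.feature_names()].isna().any().any()
    return df


_META_COLS = ("target", "target_truth", "subject_id", "activity")


def split_feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything except target/meta)."""
    return [c for c in table.columns if c not in _META_COLS]


def columns_for_combo(columns: list[str], combo: str) -> list[str]:
    """Restrict feature columns to a sensor combination.

    ``imu`` keeps accelerometer/gyroscope statistics and their derived
    lag/rolling columns; ``emg`` keeps the EMG channel and EMGsum families;
    ``imu+emg`` keeps everything.
    """
    if combo == "imu+emg":
        return list(columns)
    if combo == "imu":
        return [c for c in columns if c.startswith(_IMU_PREFIXES)]
    if combo == "emg":
        return [c for c in columns if c.startswith(_EMG_PREFIXES)]
    raise ValueError(f"unknown sensor combination {combo!r}; use imu+emg, imu, or emg")


# ---------------------------------------------------------------------------
# Selection


class CorrMISelector(TransformerMixin, BaseEstimator):
    """Keep features where both |Pearson r| and mutual information exceed thresholds.

    Mutual information uses the k-nearest-neighbour (KSG) continuous
    estimator in nats (k = 3 by default) with seeded tie-breaking jitter, so
    results are deterministic for a fixed ``random_state``.  Zero-variance
    features get r = 0 and are never kept.

    Parameters
    ----------
    r_threshold, mi_threshold : float
        Keep a feature only if |r| > r_threshold AND mi > mi_threshold.
    n_neighbors : int
        k for the KSG estimator.
    random_state : int
        Seed for the estimator's tie-breaking jitter.
    """

    def __init__(
        self,
        r_threshold: float = 0.1,
        mi_threshold: float = 0.1,
        n_neighbors: int = 3,
        random_state: int = 0,
    ):
        self.r_threshold = r_threshold
        self.mi_threshold = mi_threshold
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y):
        X, names = _as_matrix(X)
        y = np.asarray(y, float).ravel()
        n = X.shape[0]
        if n != len(y):
            raise ValueError("X and y row counts differ")
        if n <= self.n_neighbors:
            raise ValueError(
                f"need more rows ({n}) than MI neighbours ({self.n_neighbors})"
            )
        if np.var(y) == 0:
            raise ValueError("target has zero variance; correlations undefined")
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt(np.mean(xc**2, axis=0))
        sy = np.sqrt(np.mean(yc**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(sx > 0, (xc * yc[:, None]).mean(axis=0) / (sx * sy + (sx == 0)), 0.0)
        mi = mutual_info_regression(
            X, y, n_neighbors=self.n_neighbors, random_state=self.random_state
        )
        self.feature_names_in_ = np.asarray(names)
        self.n_features_in_ = X.shape[1]
        self.pearson_r_ = r
        self.mutual_info_ = mi
        self.support_ = (np.abs(r) > self.r_threshold) & (mi > self.mi_threshold)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        return self.support_

    def result(self) -> pd.DataFrame:
        """Per-feature report: feature, pearson_r, mutual_info, kept."""
        return pd.DataFrame(
            {
                "feature": self.feature_names_in_,
                "pearson_r": self.pearson_r_,
                "mutual_info": self.mutual_info_,
                "kept": self.support_,
            }
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def select_features(
    table: pd.DataFrame,
    r_threshold: float = 0.1,
    mi_threshold: float = 0.1,
    random_state: int = 0,
) -> pd.DataFrame:
    """Per-feature |r| / MI screening of a feature table against its target."""
    cols = split_feature_columns(table)
    if len(table) < 10:
        raise ValueError("feature selection needs at least 10 rows")
    sel = CorrMISelector(
        r_threshold=r_threshold, mi_threshold=mi_threshold, random_state=random_state
    )
    sel.fit(table[cols], table["target"])
    return sel.result()


# ---------------------------------------------------------------------------
# Scaling


def fit_scaler(table: pd.DataFrame, rows_mask=None, columns=None) -> MinMaxScaler:
    """Fit a [0, 1] min-max scaler on the given rows (default: all rows).

    Constant columns map to 0; transformed values are not clipped, so test
    partitions can fall outside [0, 1].
    """
    if columns is None:
        columns = split_feature_columns(table)
    sub = table if rows_mask is None else table.loc[rows_mask]
    if len(sub) == 0:
        raise ValueError("scaler fitting partition is empty")
    scaler = MinMaxScaler(clip=False)
    scaler.fit(sub[columns].to_numpy(float))
    scaler.feature_names_ = list(columns)
    return scaler


def apply_scaler(scaler: MinMaxScaler, table: pd.DataFrame) -> pd.DataFrame:
    """Scale a table's feature columns, leaving target/meta columns intact."""
    out = table.copy()
    cols = scaler.feature_names_
    out[cols] = scaler.transform(table[cols].to_numpy(float))
    return out
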