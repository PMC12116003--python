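"""LOSO cross-validation, regression metrics, and the model/sensor comparison grid.

Metrics per prediction series: MAE, MSE, RMSE, MAPE (zero targets excluded
and counted), Pearson r, and R² = 1 − SS_res/SS_tot.  The raw residual/total
sum-of-squares ratio is additionally reported as ``eq5_literal`` for
transparency — r and R² here are always the standard definitions.

Leave-one-subject-out (LOSO) evaluation trains on N−1 subjects and tests on
the held-out one, N folds in total; reported performance is the unweighted
mean of the fold metrics.  Feature selection can run once on the pooled
training corpus (``selection_mode="global"``, the default order of
operations) or inside each fold (``"per_fold"``, leakage-safe); reports
record which was used.  The min-max scaler is always fit on training rows
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    CorrMISelector,
    apply_scaler,
    columns_for_combo,
    fit_scaler,
    split_feature_columns,
)
from .nets import ModelConfig, RecurrentVO2Regressor, reshape_for_sequence

__all__ = [
    "MetricSet",
    "FoldResult",
    "LOSOReport",
    "PipelineConfig",
    "compute_metrics",
    "loso_folds",
    "VO2Pipeline",
    "run_loso",
    "unseen_evaluation",
    "run_comparison",
]


@dataclass
class MetricSet:
    """The six regression metrics plus bookkeeping fields.

    mae/rmse in mL·kg⁻¹·min⁻¹, mse in its square, mape in percent,
    r and r2 unitless.  ``mape_n_excluded`` counts zero-target samples the
    MAPE denominator cannot include (MAPE is NaN if all were excluded).
    """

    mae: float
    mse: float
    rmse: float
    mape: float
    r: float
    r2: float
    eq5_literal: float
    n: int
    mape_n_excluded: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(y, yhat) -> MetricSet:
    """Score a prediction series against its reference (equal lengths >= 2)."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} vs {len(yhat)}")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    nz = y != 0
    n_excluded = int(np.sum(~nz))
    mape = float(100.0 * np.mean(np.abs(err[nz] / y[nz]))) if nz.any() else float("nan")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(err**2))
    if ss_tot == 0:
        raise ValueError("reference series has zero variance; r/R² undefined")
    sd_hat = np.std(yhat)
    if sd_hat == 0:
        r = 0.0  # constant predictions carry no linear association
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    r2 = 1.0 - ss_res / ss_tot
    return MetricSet(
        mae=mae,
        mse=mse,
        rmse=rmse,
        mape=mape,
        r=r,
        r2=r2,
        eq5_literal=ss_res / ss_tot,
        n=len(y),
        mape_n_excluded=n_excluded,
    )


def _mean_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    """Unweighted arithmetic mean over folds; rmse recomputed from mean mse."""
    def avg(attr):
        vals = [getattr(m, attr) for m in metric_sets]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    mse = avg("mse")
    return MetricSet(
        mae=avg("mae"),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mape=avg("mape"),
        r=avg("r"),
        r2=avg("r2"),
        eq5_literal=avg("eq5_literal"),
        n=int(np.sum([m.n for m in metric_sets])),
        mape_n_excluded=int(np.sum([m.mape_n_excluded for m in metric_sets])),
    )


# ---------------------------------------------------------------------------
# LOSO machinery


def loso_folds(subject_ids) -> list[tuple[list, object]]:
    """(train_ids, test_id) per fold; every subject held out exactly once."""
    ids = list(dict.fromkeys(subject_ids))  # stable unique
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 distinct subjects")
    return [([s for s in ids if s != test], test) for test in ids]


@dataclass
class PipelineConfig:
    """Everything one LOSO run needs beyond the feature table itself."""

    model: ModelConfig = field(default_factory=ModelConfig)
    sensor_combo: str = "imu+emg"  # imu+emg | imu | emg
    r_threshold: float = 0.1
    mi_threshold: float = 0.1
    selection_mode: str = "global"  # global | per_fold
    eval_target: str = "target"  # or target_truth for parameter recovery
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_combo not in ("imu+emg", "imu", "emg"):
            raise ValueError(f"unknown sensor combination {self.sensor_combo!r}")
        if self.selection_mode not in ("global", "per_fold"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")


@dataclass
class FoldResult:
    held_out_subject: str
    metrics: MetricSet
    predictions: np.ndarray
    reference: np.ndarray
    n_features_used: int


@dataclass
class LOSOReport:
    folds: list[FoldResult]
    averaged: MetricSet
    config: dict

    def to_frame(self) -> pd.DataFrame:
        """One row per fold plus an average row (mirrors the usual report layout)."""
        rows = []
        for f in self.folds:
            d = f.metrics.as_dict()
            d["subject"] = f.held_out_subject
            rows.append(d)
        d = self.averaged.as_dict()
        d["subject"] = "average"
        rows.append(d)
        cols = ["subject", "r", "r2", "mae", "mse", "rmse", "mape"]
        return pd.DataFrame(rows)[cols]


class VO2Pipeline:
    """Select → scale → recurrent regression, fit on one training table.

    A fitted pipeline carries the selector, scaler and model and can score
    unseen tables without refitting any stage (the contract for evaluating
    whole-sequence recordings).
    """

    def __init__(self, config: PipelineConfig, selector: CorrMISelector | None = None):
        self.config = config
        self._preselected = selector

    def fit(self, table: pd.DataFrame) -> "VO2Pipeline":
        cfg = self.config
        candidates = columns_for_combo(split_feature_columns(table), cfg.sensor_combo)
        if self._preselected is not None:
            sel = self._preselected
        else:
            sel = CorrMISelector(
                r_threshold=cfg.r_threshold,
                mi_threshold=cfg.mi_threshold,
                random_state=cfg.seed,
            )
            sel.fit(table[candidates], table["target"])
        self.selector_ = sel
        kept = [c for c, k in zip(sel.feature_names_in_, sel.support_) if k]
        if not kept:
            raise ValueError(
                f"no features kept for combo {cfg.sensor_combo!r} at thresholds "
                f"r>{cfg.r_threshold}, mi>{cfg.mi_threshold}"
            )
        self.columns_ = kept
        self.scaler_ = fit_scaler(table, columns=kept)
        Xs = self.scaler_.transform(table[kept].to_numpy(float))
        model = RecurrentVO2Regressor(**asdict(cfg.model))
        if cfg.model.seq_len > 1:
            X3, y, groups = reshape_for_sequence(
                Xs, table["target"].to_numpy(), table["subject_id"].to_numpy(),
                cfg.model.seq_len,
            )
            model.fit(X3, y, groups=groups)
        else:
            model.fit(Xs, table["target"].to_numpy(),
                      groups=table["subject_id"].to_numpy())
        self.model_ = model
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns_ if c not in table.columns]
        if missing:
            raise ValueError(f"feature-space mismatch; table lacks {missing[:5]}")
        Xs = self.scaler_.transform(table[self.columns_].to_numpy(float))
        if self.config.model.seq_len > 1:
            X3, _, _ = reshape_for_sequence(
                Xs, table["target"].to_numpy(), table["subject_id"].to_numpy(),
                self.config.model.seq_len,
            )
            return self.model_.predict(X3)
        return self.model_.predict(Xs)

    def evaluate(self, table: pd.DataFrame, eval_target: str | None = None):
        target = eval_target or self.config.eval_target
        if target not in table.columns:
            raise ValueError(f"table has no {target!r} column")
        pred = self.predict(table)
        if self.config.model.seq_len > 1:
            _, y, _ = reshape_for_sequence(
                table[self.columns_].to_numpy(float),
                table[target].to_numpy(),
                table["subject_id"].to_numpy(),
                self.config.model.seq_len,
            )
        else:
            y = table[target].to_numpy(float)
        return compute_metrics(y, pred), pred


def run_loso(table: pd.DataFrame, config: PipelineConfig | None = None) -> LOSOReport:
    """Full leave-one-subject-out evaluation of the pipeline on a feature table.

    ``table`` is the concatenated per-subject feature table (must carry
    ``subject_id`` and ``target``; ``target_truth`` enables parameter-recovery
    scoring).  No held-out subject's rows ever reach feature selection
    (per-fold mode), scaler fitting, or model training.
    """
    if config is None:
        config = PipelineConfig()
    subjects = list(pd.unique(table["subject_id"]))
    folds = loso_folds(subjects)

    global_selector = None
    if config.selection_mode == "global":
        # the replicated order of operations: selection on the pooled corpus
        candidates = columns_for_combo(
            split_feature_columns(table), config.sensor_combo
        )
        global_selector = CorrMISelector(
            r_threshold=config.r_threshold,
            mi_threshold=config.mi_threshold,
            random_state=config.seed,
        )
        global_selector.fit(table[candidates], table["target"])

    results = []
    for train_ids, test_id in folds:
        train_tab = table[table["subject_id"].isin(train_ids)].reset_index(drop=True)
        test_tab = table[table["subject_id"] == test_id].reset_index(drop=True)
        assert test_id not in set(train_tab["subject_id"]), "held-out subject leaked"
        pipe = VO2Pipeline(config, selector=global_selector).fit(train_tab)
        metrics, pred = pipe.evaluate(test_tab)
        if config.model.seq_len > 1:
            _, ref, _ = reshape_for_sequence(
                test_tab[pipe.columns_].to_numpy(float),
                test_tab[config.eval_target].to_numpy(),
                test_tab["subject_id"].to_numpy(),
                config.model.seq_len,
            )
        else:
            ref = test_tab[config.eval_target].to_numpy(float)
        results.append(
            FoldResult(
                held_out_subject=str(test_id),
                metrics=metrics,
                predictions=pred,
                reference=ref,
                n_features_used=len(pipe.columns_),
            )
        )
    snapshot = {
        "arch": config.model.arch,
        "sensor_combo": config.sensor_combo,
        "selection_mode": config.selection_mode,
        "eval_target": config.eval_target,
        "r_threshold": config.r_threshold,
        "mi_threshold": config.mi_threshold,
        "seed": config.seed,
    }
    return LOSOReport(
        folds=results,
        averaged=_mean_metrics([f.metrics for f in results]),
        config=snapshot,
    )


def unseen_evaluation(
    pipeline: VO2Pipeline, unseen_table: pd.DataFrame, eval_target: str | None = None
) -> tuple[MetricSet, np.ndarray]:
    """Score a fitted pipeline on a new recording without refitting any stage."""
    return pipeline.evaluate(unseen_table, eval_target=eval_target)


def run_comparison(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    archs: tuple[str, ...] = ("lstm", "bilstm", "gru"),
    combos: tuple[str, ...] = ("imu+emg", "imu", "emg"),
) -> pd.DataFrame:
    """The architectures × sensor-combinations grid (one LOSO run per cell)."""
    if config is None:
        config = PipelineConfig()
    rows = []
    for combo in combos:
        for arch in archs:
            cfg = PipelineConfig(
                model=ModelConfig(**{**asdict(config.model), "arch": arch}),
                sensor_combo=combo,
                r_threshold=config.r_threshold,
                mi_threshold=config.mi_threshold,
                selection_mode=config.selection_mode,
                eval_target=config.eval_target,
                seed=config.seed,
            )
            report = run_loso(table, cfg)
            d = report.averaged.as_dict()
            rows.append({"sensor_combo": combo, "arch": arch, **d})
    return pd.DataFrame(rows)
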