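"""Marbling-score regression: grouped splitting, Venetian-blinds CV, and
gradient-boosted trees.

The feature table holds one row per image, several rows per meat sample
(two faces, each photographed twice).  Because duplicate rows of a sample
are near-copies, the train/test split draws *sample IDs*, never rows, so a
sample's images can never leak across the split.  Hyperparameters are
chosen by Venetian-blinds cross-validation (row ``i`` of the training table
goes to fold ``i mod k`` — interleaved "blinds"), and the headline metrics
R²(pred) and RMSEP are computed on the held-out test rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Sequence

import numpy as np
import pandas as pd
from xgboost import XGBRegressor

from .errors import InvalidInputError
from .features import FEATURE_NAMES

__all__ = [
    "SplitPlan",
    "CVPlan",
    "HyperparamGrid",
    "FitReport",
    "grouped_split",
    "venetian_blinds",
    "fit_model",
    "evaluate",
    "variable_importance",
]

REQUIRED_COLUMNS = ("sample_id", *FEATURE_NAMES, "score")


@dataclass(frozen=True)
class SplitPlan:
    """Sample-level train/test assignment."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_fraction: float
    seed: int


@dataclass(frozen=True)
class CVPlan:
    """Fold index per training row (Venetian blinds: row i -> fold (i//w) mod k)."""

    n_folds: int
    fold_of_row: np.ndarray
    window: int = 1


@dataclass(frozen=True)
class HyperparamGrid:
    """Declared search grid for the boosted-tree regressor."""

    max_depth: tuple[int, ...] = (2, 3, 4)
    learning_rate: tuple[float, ...] = (0.05, 0.1, 0.3)
    n_estimators_max: int = 500
    early_stopping_rounds: int = 15


@dataclass
class FitReport:
    """Everything the fit produced: model, metrics, importance, provenance."""

    model: Any
    best_params: dict[str, Any]
    r2_pred: float | None
    rmsep: float
    r2_cv: float | None
    rmse_cv: float
    cv_rmse_per_fold: list[float]
    importance: list[tuple[str, float]]
    split: SplitPlan
    cv: CVPlan
    seed: int
    messages: list[str] = field(default_factory=list)
    predictions: pd.DataFrame | None = None


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"feature table is missing columns: {missing}")
    scores = table["score"].to_numpy(float)
    if np.any(scores < 1.0) or np.any(scores > 7.0):
        raise InvalidInputError("scores must lie on the 1-7 sensory scale")


def grouped_split(
    table: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Randomly assign distinct sample IDs to train/test.

    ``|test| = max(1, round(test_fraction * #ids))`` with half-up rounding;
    every row of a sample falls wholly on one side.  Deterministic in seed.
    """
    if not 0 < test_fraction < 1:
        raise InvalidInputError(f"test_fraction must be in (0,1), got {test_fraction}")
    ids = pd.unique(table["sample_id"])
    if len(ids) < 2:
        raise InvalidInputError("need at least 2 distinct sample_ids to split")
    n_test = max(1, int(np.floor(test_fraction * len(ids) + 0.5)))
    if n_test >= len(ids):
        n_test = len(ids) - 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = tuple(sorted(str(ids[i]) for i in perm[:n_test]))
    train = tuple(sorted(str(ids[i]) for i in perm[n_test:]))
    return SplitPlan(train_ids=train, test_ids=test, test_fraction=test_fraction, seed=seed)


def venetian_blinds(n_rows: int, n_folds: int = 10, window: int = 1) -> CVPlan:
    """Interleaved ("Venetian blinds") fold assignment over the stored row
    order: row ``i`` goes to fold ``(i // window) mod n_folds``.

    The default blind width of 1 interleaves single rows.  When the table
    holds ``w`` consecutive replicate rows per sample, ``window=w`` keeps a
    sample's rows in one fold (sample-coherent blinds), avoiding replicate
    leakage into the CV estimate.
    """
    if n_folds < 2:
        raise InvalidInputError(f"n_folds must be >= 2, got {n_folds}")
    if window < 1:
        raise InvalidInputError(f"window must be >= 1, got {window}")
    if n_rows < n_folds * window:
        raise InvalidInputError(
            f"{n_rows} rows cannot fill {n_folds} folds of width {window}"
        )
    return CVPlan(
        n_folds=n_folds, fold_of_row=(np.arange(n_rows) // window) % n_folds, window=window
    )


def evaluate(
    predictions: Sequence[float],
    observed: Sequence[float],
    center: float | None = None,
) -> tuple[float | None, float, str | None]:
    """Return ``(r2_pred, rmsep, message)`` for held-out predictions.

    RMSEP is the root-mean-square prediction error.  R² is computed against
    the mean of the *observed held-out values* (the chemometrics convention)
    unless ``center`` supplies an alternative (e.g. the training mean).  A
    zero-variance observed vector makes R² undefined; it is returned as
    ``None`` with an explanatory message.
    """
    yhat = np.asarray(predictions, float)
    y = np.asarray(observed, float)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) < 2:
        raise InvalidInputError("predictions and observations must be equal-length 1-D, n >= 2")
    rmsep = float(np.sqrt(np.mean((y - yhat) ** 2)))
    mu = float(np.mean(y)) if center is None else float(center)
    ss_tot = float(np.sum((y - mu) ** 2))
    if ss_tot == 0.0:
        return None, rmsep, "observed values have zero variance; R2 is undefined"
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return r2, rmsep, None


def _make_regressor(params: dict[str, Any], n_estimators: int, seed: int, **kw) -> XGBRegressor:
    return XGBRegressor(
        n_estimators=n_estimators,
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **kw,
    )


def fit_model(
    table: pd.DataFrame,
    split: SplitPlan,
    cv: CVPlan | None = None,
    grid: HyperparamGrid | None = None,
    seed: int = 0,
) -> FitReport:
    """Grid-search, cross-validate and fit the boosted-tree score model.

    Training rows are the table rows (in stored order) whose sample_id is in
    ``split.train_ids``; metrics are computed on the test rows only.  For
    each (depth, learning-rate) pair the number of boosting rounds is chosen
    by early stopping on each Venetian-blinds fold; the pair with the lowest
    mean CV RMSE wins (ties go to the earlier grid entry).  The final model
    is refit on all training rows with the median early-stopped round count.
    Fixed seed implies an identical report.
    """
    _validate_table(table)
    grid = grid or HyperparamGrid()
    in_train = table["sample_id"].astype(str).isin(split.train_ids).to_numpy()
    in_test = table["sample_id"].astype(str).isin(split.test_ids).to_numpy()
    train_df = table.loc[in_train]
    test_df = table.loc[in_test]
    if len(train_df) == 0 or len(test_df) == 0:
        raise InvalidInputError("both train and test partitions must be nonempty")
    X_tr = train_df.loc[:, list(FEATURE_NAMES)].astype(float)
    y_tr = train_df["score"].to_numpy(float)
    X_te = test_df.loc[:, list(FEATURE_NAMES)].astype(float)
    y_te = test_df["score"].to_numpy(float)
    cv = cv or venetian_blinds(len(train_df), 10)
    if len(cv.fold_of_row) != len(train_df):
        raise InvalidInputError("CV plan length does not match the training rows")

    messages: list[str] = []
    if float(np.ptp(y_tr)) == 0.0:
        # Degenerate target: a single stump with no usable split predicts the
        # constant; skip the search entirely.
        warnings.warn("constant training target; fitting a constant model", stacklevel=2)
        messages.append("constant training target; model predicts the constant")
        best_params = {"max_depth": grid.max_depth[0], "learning_rate": grid.learning_rate[0]}
        model = _make_regressor(best_params, 1, seed)
        model.fit(X_tr, y_tr)
        pred_te = model.predict(X_te).astype(float)
        r2, rmsep, msg = evaluate(pred_te, y_te)
        if msg:
            messages.append(msg)
        report = FitReport(
            model=model, best_params=best_params, r2_pred=r2, rmsep=rmsep,
            r2_cv=None, rmse_cv=0.0, cv_rmse_per_fold=[], importance=_importance(model),
            split=split, cv=cv, seed=seed, messages=messages,
        )
        report.predictions = _prediction_frame(model, table, split)
        return report

    best: tuple[float, dict, list[float], list[int], np.ndarray] | None = None
    for depth, lr in product(grid.max_depth, grid.learning_rate):
        params = {"max_depth": depth, "learning_rate": lr}
        fold_rmse: list[float] = []
        fold_rounds: list[int] = []
        oof = np.full(len(train_df), np.nan)
        for k in range(cv.n_folds):
            val = cv.fold_of_row == k
            est = _make_regressor(
                params,
                grid.n_estimators_max,
                seed,
                early_stopping_rounds=grid.early_stopping_rounds,
                eval_metric="rmse",
            )
            est.fit(
                X_tr.loc[~val], y_tr[~val],
                eval_set=[(X_tr.loc[val], y_tr[val])],
                verbose=False,
            )
            p = est.predict(X_tr.loc[val]).astype(float)
            oof[val] = p
            fold_rmse.append(float(np.sqrt(np.mean((y_tr[val] - p) ** 2))))
            fold_rounds.append(int(est.best_iteration) + 1)
        mean_rmse = float(np.mean(fold_rmse))
        if best is None or mean_rmse < best[0]:
            best = (mean_rmse, params, fold_rmse, fold_rounds, oof)

    rmse_cv, best_params, cv_rmse_per_fold, rounds, oof = best
    n_final = max(1, int(np.median(rounds)))
    model = _make_regressor(best_params, n_final, seed)
    model.fit(X_tr, y_tr)
    pred_te = model.predict(X_te).astype(float)
    r2_pred, rmsep, msg = evaluate(pred_te, y_te)
    if msg:
        messages.append(msg)
    r2_cv, _, _ = evaluate(oof, y_tr)
    report = FitReport(
        model=model,
        best_params=dict(best_params, n_estimators=n_final),
        r2_pred=r2_pred,
        rmsep=rmsep,
        r2_cv=r2_cv,
        rmse_cv=rmse_cv,
        cv_rmse_per_fold=cv_rmse_per_fold,
        importance=_importance(model),
        split=split,
        cv=cv,
        seed=seed,
        messages=messages,
    )
    report.predictions = _prediction_frame(model, table, split)
    return report


def _importance(model: XGBRegressor) -> list[tuple[str, float]]:
    """Gain-based importance (total loss reduction credited to splits on
    each predictor, the tree-ensemble analogue of a VIP ranking), descending;
    ties break on feature name; features never used get weight 0."""
    raw = model.get_booster().get_score(importance_type="total_gain")
    weights = {name: float(raw.get(name, 0.0)) for name in FEATURE_NAMES}
    return sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))


def variable_importance(report: FitReport) -> list[tuple[str, float]]:
    """Ranked (feature, gain) list from a fit report."""
    return list(report.importance)


def _prediction_frame(model, table: pd.DataFrame, split: SplitPlan) -> pd.DataFrame:
    cols = [c for c in ("sample_id", "side", "duplicate_index") if c in table.columns]
    out = table.loc[:, cols].copy()
    out["observed"] = table["score"].to_numpy(float)
    out["predicted"] = model.predict(table.loc[:, list(FEATURE_NAMES)].astype(float)).astype(float)
    out["role"] = np.where(
        table["sample_id"].astype(str).isin(split.test_ids), "test", "train"
    )
    return out.reset_index(drop=True)
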