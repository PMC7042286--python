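"""Random-forest regression of environment-mean yield on the 34 features.

A 100-tree forest predicts the mean yield (quintals/ha) of an environment
from its 26 stage-windowed weather features plus 8 soil descriptors, and is
evaluated by 10-fold cross-validation on pooled out-of-fold predictions
with R², RMSE and the Pearson correlation coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

N_TREES = 100
MIN_ENVIRONMENTS = 20


@dataclass
class ModelEvaluation:
    """Pooled out-of-fold metrics plus per-fold breakdown."""

    r2: float
    rmse: float
    pearson_r: float
    fold_r2: list[float] = field(default_factory=list)
    fold_rmse: list[float] = field(default_factory=list)
    oof_predictions: pd.Series | None = None
    feature_importance: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if not -1.0 - 1e-9 <= self.pearson_r <= 1.0 + 1e-9:
            raise ValueError("pearson_r outside [-1, 1]")


def evaluate_predictions(y_true, y_pred) -> tuple[float, float, float]:
    """(R², RMSE, Pearson r) for a pair of observed/predicted vectors."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    r2 = r2_score(y_true, y_pred)
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        pearson = 0.0
    else:
        pearson = float(stats.pearsonr(y_true, y_pred).statistic)
    return float(r2), rmse, pearson


def _make_forest(seed: int) -> RandomForestRegressor:
    # hyperparameters other than tree count at library defaults
    return RandomForestRegressor(n_estimators=N_TREES, random_state=seed)


def fit(X, y, seed: int = 0) -> RandomForestRegressor:
    """Fit the 100-tree forest; deterministic given ``seed``.

    Requires at least ``MIN_ENVIRONMENTS`` rows and no missing values.
    A constant target is tolerated with a warning (the forest then predicts
    the constant).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(y) < MIN_ENVIRONMENTS:
        raise ValueError(
            f"need >= {MIN_ENVIRONMENTS} environments to fit, got {len(y)}"
        )
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values must be imputed before fitting")
    if np.std(y) == 0:
        logger.warning("target is constant; model will predict the constant")
    return _make_forest(seed).fit(X, y)


def feature_importances(model: RandomForestRegressor, feature_names) -> pd.Series:
    """Impurity-based importances as a named, unit-sum series."""
    return pd.Series(model.feature_importances_, index=list(feature_names))


def cross_validate(X, y, k: int = 10, seed: int = 0) -> ModelEvaluation:
    """k-fold cross-validation with metrics on pooled out-of-fold predictions.

    Rows are sorted by index before fold assignment so the evaluation is
    invariant to input row order.  Also refits on all rows to report feature
    importances.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, float), index=X.index)
    if len(y) < k:
        raise ValueError(f"n={len(y)} < k={k}; use a smaller k")
    order = np.argsort(X.index.to_numpy())
    X = X.iloc[order]
    y = y.iloc[order]
    Xv = X.to_numpy(float)
    yv = y.to_numpy(float)

    oof = np.full(len(yv), np.nan)
    fold_r2, fold_rmse = [], []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(Xv):
        model = _make_forest(seed).fit(Xv[train_idx], yv[train_idx])
        pred = model.predict(Xv[test_idx])
        oof[test_idx] = pred
        fr2, frmse, _ = evaluate_predictions(yv[test_idx], pred)
        fold_r2.append(fr2)
        fold_rmse.append(frmse)

    r2, rmse, pearson = evaluate_predictions(yv, oof)
    full = _make_forest(seed).fit(Xv, yv)
    return ModelEvaluation(
        r2=r2,
        rmse=rmse,
        pearson_r=pearson,
        fold_r2=fold_r2,
        fold_rmse=fold_rmse,
        oof_predictions=pd.Series(oof, index=X.index),
        feature_importance=feature_importances(full, X.columns),
    )
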