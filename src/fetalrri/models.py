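"""Regression of fetal RRI on the 13 maternal features.

Two learners, mirroring the study design: linear epsilon-insensitive
support-vector regression (the model that seeks f(x) deviating from the
targets by at most epsilon) and a random forest of bootstrap-aggregated
regression trees. Both are evaluated with leave-one-out cross-validation and
can predict an external held-out cohort.

Hyperparameter defaults follow common toolbox conventions where the study
left them unstated: for SVR, epsilon = IQR(targets)/13.49 and box constraint
C = IQR(targets)/1.349 (dispersion-scaled), with per-fold z-scoring of the
features; for RF, 100 trees, minimum leaf size 5 and one third of the
features considered per split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .types import (
    FEATURE_COLUMNS,
    CohortTable,
    ConfigurationError,
    InsufficientDataError,
)

__all__ = ["ModelConfig", "FittedModel", "fit", "loo_cross_validate", "predict_external"]


@dataclass(frozen=True)
class ModelConfig:
    """Which learner to fit and with what hyperparameters.

    ``epsilon`` / ``box_constraint`` of ``None`` mean the IQR-scaled defaults
    computed from the training targets at fit time.
    """

    kind: str = "svr"
    epsilon: float | None = None
    box_constraint: float | None = None
    standardize: bool = True
    n_trees: int = 100
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svr", "rf"):
            raise ConfigurationError(f"kind must be 'svr' or 'rf', got {self.kind!r}")
        if self.epsilon is not None and not self.epsilon > 0:
            raise ConfigurationError("epsilon must be positive")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


@dataclass(frozen=True)
class FittedModel:
    """A fitted predictor mapping a 13-feature row to fetal RRI in ms."""

    config: ModelConfig
    estimator: object
    n_train: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != len(FEATURE_COLUMNS):
            raise ConfigurationError(
                f"expected {len(FEATURE_COLUMNS)} features, got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X), dtype=float)


class _ConstantPredictor:
    """Intercept-only fallback for degenerate (zero-variance) feature matrices."""

    def __init__(self, value: float):
        self.value = value

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.value)


def _build_estimator(cfg: ModelConfig, y: np.ndarray):
    if cfg.kind == "svr":
        iqr = float(np.subtract(*np.percentile(y, [75, 25])))
        if iqr <= 0:
            iqr = max(float(np.std(y)), 1e-6)
        eps = cfg.epsilon if cfg.epsilon is not None else iqr / 13.49
        C = cfg.box_constraint if cfg.box_constraint is not None else iqr / 1.349
        svr = SVR(kernel="linear", epsilon=eps, C=max(C, 1e-6))
        if cfg.standardize:
            return Pipeline([("scale", StandardScaler()), ("svr", svr)])
        return svr
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        min_samples_leaf=cfg.min_leaf,
        max_features=1.0 / 3.0,
        bootstrap=True,
        random_state=cfg.seed,
    )


def _fit_matrix(cfg: ModelConfig, X: np.ndarray, y: np.ndarray):
    """Fit on raw arrays; degenerate features fall back to intercept-only."""
    if np.all(np.std(X, axis=0) == 0):
        import warnings

        warnings.warn(
            "all features have zero variance; fitting intercept-only model", stacklevel=3
        )
        return _ConstantPredictor(float(np.mean(y)))
    est = _build_estimator(cfg, y)
    est.fit(X, y)
    return est


def fit(model_cfg: ModelConfig, train: CohortTable) -> FittedModel:
    """Fit the configured learner on a cohort.

    Deterministic given the data (SVR) or given ``seed`` (RF). A feature
    matrix with zero variance everywhere triggers a warning and an
    intercept-only (mean-target) fallback.
    """
    if len(train) < 3:
        raise InsufficientDataError("need at least 3 records to fit a model")
    X, y = train.feature_matrix(), train.targets()
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("features must be finite")
    return FittedModel(config=model_cfg, estimator=_fit_matrix(model_cfg, X, y), n_train=len(train))


def loo_cross_validate(model_cfg: ModelConfig, cohort: CohortTable) -> np.ndarray:
    """Leave-one-out predictions: row i predicted by a model fit on all rows but i.

    Returns the n predictions in the cohort's input order. Standardization
    statistics (when enabled) are recomputed inside each fold, so the held-out
    subject leaks nothing into its own prediction.
    """
    n = len(cohort)
    if n < 3:
        raise InsufficientDataError("need at least 3 records for leave-one-out")
    X, y = cohort.feature_matrix(), cohort.targets()
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        try:
            est = _fit_matrix(model_cfg, X[mask], y[mask])
            preds[i] = float(est.predict(X[i : i + 1])[0])
        except Exception as exc:  # surface the failing fold
            raise RuntimeError(f"model fit failed in LOO fold {i} "
                               f"(subject {cohort.subject_ids[i]})") from exc
    return preds


def predict_external(fitted: FittedModel, test: CohortTable) -> np.ndarray:
    """Predict fetal RRI for an external cohort with an already-fitted model."""
    return fitted.predict(test.feature_matrix())
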