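"""Shapley attribution of fitted-model predictions to the 13 maternal features.

Interventional (marginal-expectation) Shapley values: the value of a feature
coalition S for subject x is the model prediction averaged over background
rows with the features in S replaced by x's values. Two estimators are
provided:

* ``method="permutation"`` (default) — seeded permutation sampling. Each
  sampled feature ordering contributes one telescoping chain of coalition
  evaluations, so the efficiency axiom (attributions sum to prediction minus
  mean background prediction) holds exactly, permutation by permutation.
* ``method="exact"`` — full enumeration of all 2^13 coalitions with the
  exact Shapley kernel weights; intended for small backgrounds and tests.

Summaries follow the absolute-mean convention: per feature, the mean of
|Shapley value| across subjects, with a normal-approximation 95 % CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FittedModel
from .types import FEATURE_COLUMNS, CohortTable, ConfigurationError

__all__ = ["ShapleyReport", "shapley_values", "summarize"]


@dataclass(frozen=True)
class ShapleyReport:
    """Per-feature absolute-mean Shapley values (ms) with 95 % CI."""

    feature_names: tuple[str, ...]
    mean_abs_shapley: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    values: np.ndarray  # n_subjects x n_features signed Shapley values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "mean_abs_shapley_ms": self.mean_abs_shapley,
                "ci_low_ms": self.ci_low,
                "ci_high_ms": self.ci_high,
            }
        )

    def ranking(self) -> list[str]:
        """Feature names ordered from largest to smallest mean |Shapley|."""
        order = np.argsort(self.mean_abs_shapley)[::-1]
        return [self.feature_names[i] for i in order]


def _mean_prediction(model: FittedModel, composite: np.ndarray) -> np.ndarray:
    """Predict on a (..., B, p) composite stack and average over the B axis."""
    shape = composite.shape
    flat = composite.reshape(-1, shape[-1])
    preds = model.predict(flat).reshape(shape[:-1])
    return preds.mean(axis=-1)


def _shapley_permutation(
    model: FittedModel, X: np.ndarray, B: np.ndarray, rng: np.random.Generator, n_coalitions: int
) -> np.ndarray:
    n, p = X.shape
    n_perms = max(1, math.ceil(n_coalitions / p))
    phi = np.zeros((n, p))
    for _ in range(n_perms):
        order = rng.permutation(p)
        # composite[k] = background with features order[:k] set to the subject's
        composite = np.broadcast_to(B, (n, B.shape[0], p)).copy()
        v_prev = _mean_prediction(model, composite)  # v(empty set)
        for k in range(p):
            j = order[k]
            composite[:, :, j] = X[:, j][:, None]
            v_cur = _mean_prediction(model, composite)
            phi[:, j] += v_cur - v_prev
            v_prev = v_cur
    return phi / n_perms


def _shapley_exact(model: FittedModel, X: np.ndarray, B: np.ndarray) -> np.ndarray:
    n, p = X.shape
    n_masks = 1 << p
    masks = np.arange(n_masks)
    bits = ((masks[:, None] >> np.arange(p)) & 1).astype(bool)  # n_masks x p
    sizes = bits.sum(axis=1)
    # Shapley kernel weight for adding a feature to a coalition of size s
    fact = np.array([math.factorial(k) for k in range(p + 1)], dtype=float)
    w = fact[np.arange(p)] * fact[p - 1 - np.arange(p)] / fact[p]

    phi = np.zeros((n, p))
    for i in range(n):
        # v(S) for every coalition, averaged over the background
        composite = np.where(bits[:, None, :], X[i][None, None, :], B[None, :, :])
        v = _mean_prediction(model, composite)  # length n_masks
        for j in range(p):
            without = masks[~bits[:, j]]
            phi[i, j] = float(np.sum(w[sizes[without]] * (v[without | (1 << j)] - v[without])))
    return phi


def shapley_values(
    fitted: FittedModel,
    cohort: CohortTable,
    background: CohortTable | None = None,
    seed: int = 0,
    method: str = "permutation",
    n_coalitions: int = 1024,
) -> np.ndarray:
    """Estimate the n x 13 matrix of signed Shapley values, in ms.

    ``background`` defaults to the cohort itself (the usual choice when
    explaining a model on its own training set). For a linear model with an
    independent background, feature j's value for subject i converges to
    ``w_j * (x_ij - mean background x_j)``.
    """
    if background is None:
        background = cohort
    X = cohort.feature_matrix()
    B = background.feature_matrix()
    if B.shape[0] < 5:
        warnings.warn(
            f"background has only {B.shape[0]} rows; Shapley estimates will be high-variance",
            stacklevel=2,
        )
    if method == "permutation":
        rng = np.random.default_rng(seed)
        return _shapley_permutation(fitted, X, B, rng, n_coalitions)
    if method == "exact":
        return _shapley_exact(fitted, X, B)
    raise ConfigurationError(f"unknown method {method!r}")


def summarize(
    matrix: np.ndarray, feature_names: tuple[str, ...] = FEATURE_COLUMNS
) -> ShapleyReport:
    """Absolute-mean summary across subjects with a 95 % CI per feature.

    CI = mean(|phi|) +/- 1.96 * SE(|phi|), clipped at 0. With a single subject
    the CI is degenerate (equal to the point value) and a warning is emitted.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    if m.size == 0:
        raise ConfigurationError("empty Shapley matrix")
    if m.shape[1] != len(feature_names):
        raise ConfigurationError("matrix width must match feature_names")
    a = np.abs(m)
    mean_abs = a.mean(axis=0)
    if m.shape[0] < 2:
        warnings.warn("single-subject matrix: confidence interval is degenerate", stacklevel=2)
        se = np.zeros_like(mean_abs)
    else:
        se = a.std(axis=0, ddof=1) / np.sqrt(m.shape[0])
    ci_low = np.clip(mean_abs - 1.96 * se, 0.0, None)
    ci_high = mean_abs + 1.96 * se
    return ShapleyReport(
        feature_names=tuple(feature_names),
        mean_abs_shapley=mean_abs,
        ci_low=ci_low,
        ci_high=ci_high,
        values=m,
    )
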