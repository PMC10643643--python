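"""Evaluation statistics for fetal-RRI predictions.

Per subject: the absolute percentage error
``Error(%) = 100 |predicted - actual| / actual`` and a <= 5 % acceptability
rule. Aggregate: RMSE, Spearman rank correlation between predicted and actual
values (two-sided p, 0.05 significance level), Bland-Altman agreement
(mean difference and mean +/- 1.96 SD limits, differences taken as
predicted - actual so a negative mean means underestimation), and the
correlation of per-subject error with gestational age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import DegenerateInputError, InsufficientDataError, SchemaError

__all__ = [
    "PredictionResult",
    "error_percentage",
    "acceptability",
    "rmse",
    "spearman",
    "bland_altman",
    "error_vs_ga",
    "evaluate_predictions",
    "format_error_pct",
    "ACCEPTABILITY_THRESHOLD_PCT",
]

#: Error percentage at or below which a per-subject prediction is acceptable.
ACCEPTABILITY_THRESHOLD_PCT = 5.0


def error_percentage(predicted: float, actual: float) -> float:
    """Absolute prediction error as a percentage of the actual value."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if np.any(actual <= 0):
        raise DegenerateInputError("actual fRRI must be positive")
    return 100.0 * np.abs(predicted - actual) / actual


def format_error_pct(err: float) -> str:
    """Report-style rounding: one decimal below 10 %, integer above."""
    return f"{err:.1f}" if err < 10 else f"{err:.0f}"


def acceptability(
    errors_pct, subject_ids=None, threshold: float = ACCEPTABILITY_THRESHOLD_PCT
) -> tuple[int, list]:
    """Count errors at or below ``threshold`` (inclusive); list the rejected ids.

    Returns ``(accepted_count, rejected_ids)``; ids default to 0-based indices.
    """
    errors = np.asarray(list(errors_pct), dtype=float)
    ids = list(subject_ids) if subject_ids is not None else list(range(errors.size))
    if len(ids) != errors.size:
        raise SchemaError("subject_ids length must match errors length")
    ok = errors <= threshold
    return int(ok.sum()), [i for i, good in zip(ids, ok) if not good]


def rmse(actual, predicted) -> float:
    """Root mean square error between paired values, in the input units (ms)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise SchemaError("actual and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    The p-value uses the t-distribution approximation. Zero variance in either
    input makes the correlation undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def bland_altman(actual, predicted) -> tuple[float, float, float, float]:
    """Bland-Altman agreement of predicted vs actual values.

    Differences ``d = predicted - actual``; limits of agreement are
    ``mean(d) +/- 1.96 * SD(d)`` with the sample (n-1) SD. Returns
    ``(mean_diff, upper, lower, pct_within)`` where ``pct_within`` is the
    percentage of differences strictly inside the limits. Plot abscissa, when
    drawn, is the pairwise mean of the two measurements.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size < 3:
        raise SchemaError("need >= 3 equal-length pairs")
    d = p - a
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    upper, lower = mean_diff + 1.96 * sd, mean_diff - 1.96 * sd
    pct_within = float(100.0 * np.mean((d > lower) & (d < upper)))
    return mean_diff, upper, lower, pct_within


@dataclass(frozen=True)
class PredictionResult:
    """Per-subject predictions plus the aggregate evaluation statistics."""

    subject_ids: list
    ga_weeks: np.ndarray
    actual_frri_ms: np.ndarray
    predicted_frri_ms: np.ndarray
    error_pct: np.ndarray
    rmse_ms: float
    spearman_r: float
    spearman_p: float
    ba_mean_diff_ms: float
    ba_upper_ms: float
    ba_lower_ms: float
    pct_within_limits: float
    n: int

    def aggregate_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse_ms": self.rmse_ms,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "ba_mean_diff_ms": self.ba_mean_diff_ms,
            "ba_upper_ms": self.ba_upper_ms,
            "ba_lower_ms": self.ba_lower_ms,
            "pct_within_limits": self.pct_within_limits,
        }


def evaluate_predictions(
    subject_ids, ga_weeks, actual, predicted
) -> PredictionResult:
    """Assemble the full per-subject + aggregate evaluation of a prediction run."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ga = np.asarray(ga_weeks, dtype=float)
    ids = list(subject_ids)
    if not (len(ids) == a.size == p.size == ga.size):
        raise SchemaError("subject_ids, ga_weeks, actual, predicted must align")
    err = error_percentage(p, a)
    mean_diff, upper, lower, pct_within = bland_altman(a, p)
    r, pv = spearman(a, p)
    return PredictionResult(
        subject_ids=ids,
        ga_weeks=ga,
        actual_frri_ms=a,
        predicted_frri_ms=p,
        error_pct=err,
        rmse_ms=rmse(a, p),
        spearman_r=r,
        spearman_p=pv,
        ba_mean_diff_ms=mean_diff,
        ba_upper_ms=upper,
        ba_lower_ms=lower,
        pct_within_limits=pct_within,
        n=a.size,
    )


def error_vs_ga(result: PredictionResult) -> tuple[float, float]:
    """Spearman correlation of per-subject error % against gestational age.

    A near-zero correlation indicates prediction accuracy does not drift over
    gestation. Missing GA or constant errors raise.
    """
    if result.ga_weeks.size != result.error_pct.size or not np.all(np.isfinite(result.ga_weeks)):
        raise SchemaError("gestational age must be present and finite for all subjects")
    return spearman(result.error_pct, result.ga_weeks)
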