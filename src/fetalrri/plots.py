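"""Optional figures: Bland-Altman, prediction scatter, Shapley bar chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import PredictionResult
from .shapley import ShapleyReport

__all__ = ["bland_altman_plot", "prediction_scatter", "shapley_bar_plot"]


def bland_altman_plot(result: PredictionResult, path: str | Path) -> None:
    """Differences (predicted - actual) against pairwise means, with limits."""
    means = (result.actual_frri_ms + result.predicted_frri_ms) / 2.0
    diffs = result.predicted_frri_ms - result.actual_frri_ms
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.7)
    for y, style in ((result.ba_mean_diff_ms, "-"), (result.ba_upper_ms, "--"), (result.ba_lower_ms, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of actual and predicted fRRI (ms)")
    ax.set_ylabel("predicted − actual fRRI (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def prediction_scatter(result: PredictionResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.actual_frri_ms, result.predicted_frri_ms, s=18, alpha=0.7)
    lims = [
        min(result.actual_frri_ms.min(), result.predicted_frri_ms.min()),
        max(result.actual_frri_ms.max(), result.predicted_frri_ms.max()),
    ]
    ax.plot(lims, lims, "k--", linewidth=1)
    ax.set_xlabel("actual fRRI (ms)")
    ax.set_ylabel("predicted fRRI (ms)")
    ax.set_title(f"Spearman r = {result.spearman_r:.2f}, RMSE = {result.rmse_ms:.1f} ms")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def shapley_bar_plot(report: ShapleyReport, path: str | Path) -> None:
    """Mean |Shapley| per feature with 95 % CI whiskers, largest first."""
    df = report.to_frame().sort_values("mean_abs_shapley_ms", ascending=True)
    err = [
        df["mean_abs_shapley_ms"] - df["ci_low_ms"],
        df["ci_high_ms"] - df["mean_abs_shapley_ms"],
    ]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.barh(df["feature"], df["mean_abs_shapley_ms"], xerr=err, capsize=3)
    ax.set_xlabel("mean |Shapley value| (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
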