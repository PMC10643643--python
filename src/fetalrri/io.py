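"""File formats and configuration.

CSV is the interchange format throughout: two-column ``time_s, amplitude``
(or single-column plus a sampling rate) for ECG waveforms, the canonical
16-column cohort schema for feature tables, and ``subject_id, actual,
predicted`` triplets for predictions. Reports are JSON. Pipeline
configuration is YAML; the seed and a config hash are embedded in every
written report so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import COHORT_COLUMNS, CohortTable, ECGSignal, SchemaError

__all__ = [
    "read_ecg",
    "write_ecg",
    "read_cohort",
    "write_cohort",
    "write_predictions",
    "read_predictions",
    "write_report",
    "load_config",
    "config_hash",
]

#: tolerable relative jitter of the time column of an ECG CSV
_MAX_REL_JITTER = 1e-3


def read_ecg(path: str | Path, fs: float | None = None, label: str = "maternal") -> ECGSignal:
    """Read an ECG waveform CSV.

    Two columns are interpreted as ``time_s, amplitude`` (sampling rate
    inferred from the median time step, time column validated for
    uniformity); one column requires an explicit ``fs``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        amp = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2  # header + 1-based
            raise SchemaError(f"{path}: time column not strictly increasing at line {bad}")
        jitter = float(np.max(np.abs(dt - np.median(dt))) / np.median(dt))
        if jitter > _MAX_REL_JITTER:
            raise SchemaError(
                f"{path}: non-uniform time column (relative jitter {jitter:.2e})"
            )
        return ECGSignal(samples=amp, fs=1.0 / float(np.median(dt)), label=label, start_time_s=float(t[0]))
    if fs is None:
        raise SchemaError(f"{path}: single-column ECG requires an explicit sampling rate")
    return ECGSignal(samples=df.iloc[:, 0].to_numpy(dtype=float), fs=fs, label=label)


def write_ecg(sig: ECGSignal, path: str | Path) -> None:
    """Write a waveform as a two-column ``time_s, amplitude`` CSV."""
    pd.DataFrame({"time_s": sig.times_s, "amplitude": sig.samples}).to_csv(path, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Read the canonical cohort CSV; unknown columns are ignored as metadata.

    Missing required columns raise a :class:`SchemaError` naming them, as do
    duplicate subject ids and empty files.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return CohortTable.from_frame(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    # %.17g guarantees exact float64 round-tripping through the CSV
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_predictions(
    subject_ids, actual, predicted, path: str | Path, error_pct=None
) -> None:
    df = pd.DataFrame(
        {"subject_id": list(subject_ids), "actual_frri_ms": actual, "predicted_frri_ms": predicted}
    )
    if error_pct is not None:
        df["error_pct"] = error_pct
    df.to_csv(path, index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV (``subject_id, actual_frri_ms, predicted_frri_ms``)."""
    df = pd.read_csv(path)
    required = ["subject_id", "actual_frri_ms", "predicted_frri_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    return df


def write_report(report: dict, path: str | Path, config: dict | None = None, seed: int | None = None) -> None:
    """Write a JSON report with reproducibility metadata (seed + config hash)."""
    payload = dict(report)
    payload["_meta"] = {
        "seed": seed,
        "config_sha256": config_hash(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a YAML mapping")
    return cfg
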