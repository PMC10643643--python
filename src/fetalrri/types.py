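"""Core domain types shared across the pipeline.

The pipeline moves through three signal-level containers — :class:`ECGSignal`
(raw uniformly sampled waveform), :class:`BeatSeries` (detected R-peak times and
normalized amplitudes), :class:`RRISeries` (successive R-peak differences in
ms) — and one table-level container, :class:`CohortTable`, holding the
13 maternal features plus the fetal target (mean fetal RR interval, ms) per
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ParameterError",
    "DegenerateInputError",
    "InsufficientDataError",
    "SchemaError",
    "ECGSignal",
    "BeatSeries",
    "RRISeries",
    "SubjectRecord",
    "CohortTable",
    "FEATURE_COLUMNS",
    "COHORT_COLUMNS",
]


class ConfigurationError(ValueError):
    """A spec/config field violates its invariant; the message names the field."""


class ParameterError(ValueError):
    """An operation parameter is outside its valid range."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero signal)."""


class InsufficientDataError(ValueError):
    """Too few samples/beats/records for the requested computation."""


class SchemaError(ValueError):
    """A table is missing required columns or breaks a uniqueness constraint."""


#: Fixed feature order fed to the regression models: maternal age and weight,
#: time-domain HRV (SDNN, SDHR), the four RRI band powers, the four R-wave
#: amplitude band powers, and mean maternal RRI.
FEATURE_COLUMNS: tuple[str, ...] = (
    "age_years",
    "weight_kg",
    "sdnn_ms",
    "sdhr_bpm",
    "vlf",
    "lf",
    "hf",
    "vhf",
    "rw_vlf",
    "rw_lf",
    "rw_hf",
    "rw_vhf",
    "rri_ms",
)

#: Canonical CSV column order for a cohort table.
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "ga_weeks",
    "age_years",
    "weight_kg",
    "rri_ms",
    "sdnn_ms",
    "sdhr_bpm",
    "vlf",
    "lf",
    "hf",
    "vhf",
    "rw_vlf",
    "rw_lf",
    "rw_hf",
    "rw_vhf",
    "frri_ms",
)


@dataclass(frozen=True)
class ECGSignal:
    """A uniformly sampled single-channel ECG waveform.

    Parameters
    ----------
    samples
        Amplitude values in arbitrary units.
    fs
        Sampling rate in Hz (the study recordings were sampled at 1 kHz).
    label
        ``"maternal"`` or ``"fetal"``; informational only.
    start_time_s
        Absolute time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = "maternal"
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ConfigurationError("fs must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ConfigurationError("samples must be a 1-D array with >= 2 values")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatSeries:
    """Detected R-peak times (s) and normalized amplitudes.

    Amplitudes are on the post-normalization scale, i.e. in (0, 1] when the
    signal was divided by its maximum before peak detection.
    """

    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    fs_source: float

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        a = np.asarray(self.peak_amplitudes, dtype=float)
        object.__setattr__(self, "peak_times_s", t)
        object.__setattr__(self, "peak_amplitudes", a)
        if t.shape != a.shape:
            raise ConfigurationError("peak_times_s and peak_amplitudes must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ConfigurationError("peak_times_s must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_times_s.size)


@dataclass(frozen=True)
class RRISeries:
    """RR-interval tachogram: ``intervals_ms[i]`` spans beats ``i`` and ``i+1``.

    ``times_s`` holds the time of the *later* beat of each pair, the abscissa
    used for the Lomb-Scargle periodogram of the unevenly sampled series.
    """

    times_s: np.ndarray
    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.intervals_ms, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intervals_ms", v)
        if t.shape != v.shape:
            raise ConfigurationError("times_s and intervals_ms must have equal length")
        if v.size and np.any(v <= 0):
            raise ConfigurationError("all intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def heart_rate_bpm(self) -> np.ndarray:
        """Instantaneous heart rate, 60000 / RRI."""
        return 60000.0 / self.intervals_ms


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: 13 maternal features + gestational age + actual fetal RRI."""

    subject_id: str
    ga_weeks: float
    features: np.ndarray  # ordered as FEATURE_COLUMNS
    actual_frri_ms: float

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", f)
        if f.shape != (len(FEATURE_COLUMNS),):
            raise ConfigurationError(
                f"features must have length {len(FEATURE_COLUMNS)}, got {f.shape}"
            )
        if not np.all(np.isfinite(f)):
            raise ConfigurationError("features must be finite")
        if not self.actual_frri_ms > 0:
            raise ConfigurationError("actual_frri_ms must be positive")


class CohortTable:
    """An ordered collection of :class:`SubjectRecord` with unique ids.

    Internally a :class:`pandas.DataFrame` with the canonical column order
    (:data:`COHORT_COLUMNS`); the feature matrix / target vector accessors
    return plain numpy arrays in the fixed feature order.
    """

    def __init__(self, records: Sequence[SubjectRecord]):
        ids = [r.subject_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate subject_id: {dupes}")
        self._records = list(records)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        records = [
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                ga_weeks=float(row["ga_weeks"]),
                features=np.array([row[c] for c in FEATURE_COLUMNS], dtype=float),
                actual_frri_ms=float(row["frri_ms"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self._records:
            d = {"subject_id": r.subject_id, "ga_weeks": r.ga_weeks, "frri_ms": r.actual_frri_ms}
            d.update(dict(zip(FEATURE_COLUMNS, r.features)))
            rows.append(d)
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    @property
    def records(self) -> list[SubjectRecord]:
        return list(self._records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self._records]

    @property
    def ga_weeks(self) -> np.ndarray:
        return np.array([r.ga_weeks for r in self._records])

    def feature_matrix(self) -> np.ndarray:
        return np.vstack([r.features for r in self._records]) if self._records else np.empty((0, len(FEATURE_COLUMNS)))

    def targets(self) -> np.ndarray:
        return np.array([r.actual_frri_ms for r in self._records])

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self._records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return len(self) == len(other) and all(
            a.subject_id == b.subject_id
            and a.ga_weeks == b.ga_weeks
            and a.actual_frri_ms == b.actual_frri_ms
            and np.array_equal(a.features, b.features)
            for a, b in zip(self, other)
        )
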