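"""Maternal HRV / R-wave-amplitude-variability features and subject assembly.

Thirteen maternal features are computed per 5-min segment and averaged across
segments: age, weight, SDNN, SDHR, the four Lomb-Scargle band powers of the
RR-interval tachogram (VLF/LF/HF/VHF) and of the R-wave amplitude series
(RWVLF/RWLF/RWHF/RWVHF), and mean RRI. The prediction target is the mean
fetal RRI over the same segments.

Band powers are integrated power over half-open frequency bands, computed on
the unevenly sampled beat-indexed series directly (no resampling) via the
Lomb-Scargle periodogram converted to power-spectral-density scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .ecg import beats_to_rri
from .types import (
    FEATURE_COLUMNS,
    BeatSeries,
    ConfigurationError,
    InsufficientDataError,
    RRISeries,
    SubjectRecord,
)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "SegmentFeatures",
    "time_domain_hrv",
    "lomb_scargle_band_power",
    "rwav_band_power",
    "segment_features",
    "assemble_subject",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ConfigurationError(f"band {self.name}: need 0 < f_low < f_high")


#: The four variability bands. VLF needs >= 5 min of data for proper
#: assessment, which is why the pipeline's default window is 300 s.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("VLF", 0.0033, 0.04),
    BandDefinition("LF", 0.04, 0.15),
    BandDefinition("HF", 0.15, 0.4),
    BandDefinition("VHF", 0.4, 0.9),
)


@dataclass(frozen=True)
class SegmentFeatures:
    """The 11 ECG-derived maternal features of one analysis segment.

    Band powers carry integrated-power units: ms^2 for the RRI bands,
    (normalized amplitude)^2 for the R-wave bands.
    """

    rri_mean: float
    sdnn: float
    sdhr: float
    vlf: float
    lf: float
    hf: float
    vhf: float
    rw_vlf: float
    rw_lf: float
    rw_hf: float
    rw_vhf: float
    segment_start_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.rri_mean > 0:
            raise ConfigurationError("rri_mean must be positive")
        for name in ("sdnn", "sdhr", "vlf", "lf", "hf", "vhf", "rw_vlf", "rw_lf", "rw_hf", "rw_vhf"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def time_domain_hrv(rri: RRISeries) -> tuple[float, float, float]:
    """Mean RRI (ms), SDNN (ms) and SDHR (bpm) of an RR-interval series.

    SDNN is the sample standard deviation (n-1 denominator) of the intervals;
    SDHR the sample SD of the instantaneous heart rate 60000/RRI.
    """
    if len(rri) < 2:
        raise InsufficientDataError("need at least 2 intervals for time-domain HRV")
    iv = rri.intervals_ms
    return float(np.mean(iv)), float(np.std(iv, ddof=1)), float(np.std(rri.heart_rate_bpm, ddof=1))


def lomb_scargle_band_power(
    times_s: np.ndarray,
    values: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    oversample: int = 4,
) -> dict[str, float]:
    """Integrated Lomb-Scargle power of an uneven series in each band.

    The series is mean-centered, the periodogram evaluated on a grid from
    ``max(1/T, min f_low)`` to ``max f_high`` with spacing ``1/(oversample*T)``,
    converted to one-sided PSD scale (``2 P T / N``, which reproduces the FFT
    periodogram density on even sampling), and trapezoid-integrated over each
    half-open band. Returns ``{band name: power >= 0}``.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ConfigurationError("times and values must have equal length")
    if t.size < 8:
        raise InsufficientDataError("need at least 8 samples for band-power estimation")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    y = y - y.mean()
    if np.allclose(y, 0.0):
        return {b.name: 0.0 for b in bands}

    T = t[-1] - t[0]
    f_min = max(1.0 / T, min(b.f_low for b in bands))
    f_max = max(b.f_high for b in bands)
    df = 1.0 / (oversample * T)
    freqs = np.arange(f_min, f_max + df, df)
    power = lombscargle(t, y, 2 * np.pi * freqs, normalize=False)
    density = 2.0 * power * T / t.size  # one-sided PSD scale

    out: dict[str, float] = {}
    for b in bands:
        mask = (freqs >= b.f_low) & (freqs < b.f_high)
        out[b.name] = float(np.trapezoid(density[mask], freqs[mask])) if mask.sum() > 1 else 0.0
    return out


def rwav_band_power(
    beats: BeatSeries, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, float]:
    """Band powers of the R-wave amplitude series (respiration-driven variability).

    Only frequency-domain amplitude-variability features are produced; the
    beat-indexed amplitude series is analyzed exactly like the RRI tachogram.
    """
    return lomb_scargle_band_power(beats.peak_times_s, beats.peak_amplitudes, bands)


def segment_features(
    beats: BeatSeries,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    segment_start_s: float | None = None,
) -> SegmentFeatures:
    """All 11 ECG-derived features of one maternal segment's beat series."""
    rri = beats_to_rri(beats)
    rri_mean, sdnn, sdhr = time_domain_hrv(rri)
    bp = lomb_scargle_band_power(rri.times_s, rri.intervals_ms, bands)
    rw = rwav_band_power(beats, bands)
    return SegmentFeatures(
        rri_mean=rri_mean,
        sdnn=sdnn,
        sdhr=sdhr,
        vlf=bp["VLF"],
        lf=bp["LF"],
        hf=bp["HF"],
        vhf=bp["VHF"],
        rw_vlf=rw["VLF"],
        rw_lf=rw["LF"],
        rw_hf=rw["HF"],
        rw_vhf=rw["VHF"],
        segment_start_s=beats.peak_times_s[0] if segment_start_s is None else segment_start_s,
    )


_SEGMENT_TO_FEATURE = {
    "sdnn_ms": "sdnn",
    "sdhr_bpm": "sdhr",
    "vlf": "vlf",
    "lf": "lf",
    "hf": "hf",
    "vhf": "vhf",
    "rw_vlf": "rw_vlf",
    "rw_lf": "rw_lf",
    "rw_hf": "rw_hf",
    "rw_vhf": "rw_vhf",
    "rri_ms": "rri_mean",
}


def assemble_subject(
    maternal_segments: list[SegmentFeatures],
    fetal_rri_means: list[float],
    age_years: float,
    weight_kg: float,
    subject_id: str = "S1",
    ga_weeks: float = 30.0,
) -> SubjectRecord:
    """Average per-segment features into one subject record.

    One or two maternal segments are averaged feature-wise; the target is the
    mean fetal RRI over the same number of fetal segments. A single segment
    passes through unchanged (the single-window fallback used for test-cohort
    subjects whose recording supported only one 5-min extraction).
    """
    if not maternal_segments:
        raise InsufficientDataError("need at least one maternal segment")
    if len(maternal_segments) != len(fetal_rri_means):
        raise ConfigurationError(
            f"maternal segment count {len(maternal_segments)} != fetal segment count "
            f"{len(fetal_rri_means)}"
        )
    feats = np.empty(len(FEATURE_COLUMNS))
    for j, col in enumerate(FEATURE_COLUMNS):
        if col == "age_years":
            feats[j] = age_years
        elif col == "weight_kg":
            feats[j] = weight_kg
        else:
            feats[j] = float(
                np.mean([getattr(s, _SEGMENT_TO_FEATURE[col]) for s in maternal_segments])
            )
    return SubjectRecord(
        subject_id=subject_id,
        ga_weeks=ga_weeks,
        features=feats,
        actual_frri_ms=float(np.mean(fetal_rri_means)),
    )
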