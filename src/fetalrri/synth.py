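"""Synthetic maternal/fetal ECG and cohort generators with known ground truth.

Two generators back every downstream test:

* :func:`generate_ecg` builds a single-channel ECG by integral pulse frequency
  modulation (IPFM): an instantaneous RR interval ``RRI(t) = mean_rri_ms +
  sum_k a_k sin(2 pi f_k t + phi_k)`` drives beat placement, a Gaussian QRS
  template is stamped at each beat with respiration-style amplitude
  modulation, and baseline wander plus white noise are added. The exact beat
  times and amplitudes used are returned as ground truth.
* :func:`generate_cohort` draws maternal feature vectors from independent
  Gaussians (truncated at physiological floors) and computes the fetal RRI
  target from a known linear mapping plus Gaussian noise, enabling
  parameter-recovery tests of the regression stage.

Identical spec + seed give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    FEATURE_COLUMNS,
    BeatSeries,
    CohortTable,
    ConfigurationError,
    ECGSignal,
    SubjectRecord,
)

__all__ = [
    "SyntheticECGSpec",
    "SyntheticCohortSpec",
    "generate_ecg",
    "generate_cohort",
    "DEFAULT_FEATURE_MEANS",
    "DEFAULT_FEATURE_SDS",
    "DEFAULT_WEIGHTS",
    "DEFAULT_INTERCEPT_MS",
]

# Simulator defaults for the maternal feature distribution, in FEATURE_COLUMNS
# order: age (y), weight (kg), SDNN (ms), SDHR (bpm), VLF/LF/HF/VHF RRI band
# power, RW-VLF/LF/HF/VHF amplitude band power, mean RRI (ms). Values are
# typical of mid-gestation pregnancy cohorts.
DEFAULT_FEATURE_MEANS = np.array(
    [34.0, 60.0, 34.0, 3.6, 664.0, 229.0, 254.0, 44.0, 0.037, 0.019, 0.056, 0.016, 763.0]
)
DEFAULT_FEATURE_SDS = np.array(
    [5.3, 8.4, 14.0, 1.3, 565.0, 223.0, 356.0, 146.0, 0.025, 0.011, 0.040, 0.012, 114.0]
)

# Default generative mapping feature -> fetal RRI: a weak dependence on
# maternal RRI, age, SDHR and HF power. With the feature distribution above
# this yields fetal RRI ~ 412 +/- 22 ms, the typical mid-gestation range.
DEFAULT_WEIGHTS = np.zeros(len(FEATURE_COLUMNS))
DEFAULT_WEIGHTS[FEATURE_COLUMNS.index("rri_ms")] = 0.15
DEFAULT_WEIGHTS[FEATURE_COLUMNS.index("age_years")] = 1.0
DEFAULT_WEIGHTS[FEATURE_COLUMNS.index("sdhr_bpm")] = 3.0
DEFAULT_WEIGHTS[FEATURE_COLUMNS.index("hf")] = 0.02
DEFAULT_INTERCEPT_MS = 412.0 - float(DEFAULT_WEIGHTS @ DEFAULT_FEATURE_MEANS)


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Parameters of one simulated ECG channel.

    ``band_modulations`` lists ``(center_freq_hz, rri_amplitude_ms)`` sinusoids
    added to the instantaneous RR interval; ``rwa_modulations`` lists
    ``(center_freq_hz, relative_amplitude)`` sinusoids modulating the R-wave
    height around 1. Modulation phases are drawn from ``seed``.
    """

    duration_s: float = 600.0
    fs: float = 1000.0
    mean_rri_ms: float = 763.0
    band_modulations: tuple[tuple[float, float], ...] = ()
    rwa_modulations: tuple[tuple[float, float], ...] = ()
    qrs_width_ms: float = 30.0
    baseline_wander_amp: float = 0.0
    baseline_wander_freq_hz: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ConfigurationError("fs must be positive")
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be positive")
        if not self.mean_rri_ms > 0:
            raise ConfigurationError("mean_rri_ms must be positive")
        if not self.qrs_width_ms > 0:
            raise ConfigurationError("qrs_width_ms must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        beat_nyquist = 0.5 * 1000.0 / self.mean_rri_ms
        for f, _ in self.band_modulations:
            if f >= beat_nyquist:
                raise ConfigurationError(
                    f"band_modulations frequency {f} Hz is at or above the beat-rate "
                    f"Nyquist {beat_nyquist:.3f} Hz"
                )
        amp_sum = sum(a for _, a in self.band_modulations)
        if amp_sum >= self.mean_rri_ms:
            raise ConfigurationError(
                "band_modulations amplitudes must sum below mean_rri_ms so intervals stay positive"
            )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one simulated cohort with a known feature -> fRRI mapping.

    ``weights`` (ms per feature unit) and ``intercept`` define
    ``fRRI = intercept + weights . features + N(0, noise_sd)``.
    """

    n_subjects: int = 150
    feature_means: np.ndarray = field(default_factory=lambda: DEFAULT_FEATURE_MEANS.copy())
    feature_sds: np.ndarray = field(default_factory=lambda: DEFAULT_FEATURE_SDS.copy())
    weights: np.ndarray = field(default_factory=lambda: DEFAULT_WEIGHTS.copy())
    intercept: float = DEFAULT_INTERCEPT_MS
    noise_sd: float = 10.0
    ga_range_weeks: tuple[float, float] = (19.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(FEATURE_COLUMNS)
        for name in ("feature_means", "feature_sds", "weights"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (p,):
                raise ConfigurationError(f"{name} must have length {p}")
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if np.any(self.feature_sds < 0):
            raise ConfigurationError("feature_sds must be non-negative elementwise")
        if not self.ga_range_weeks[0] <= self.ga_range_weeks[1]:
            raise ConfigurationError("ga_range_weeks must be (min, max) with min <= max")


def _beat_times_ipfm(spec: SyntheticECGSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """IPFM beat placement: integrate the instantaneous beat rate and emit a
    beat at each integer crossing. Returns (beat_times_s, modulation_phases)."""
    phases = rng.uniform(0, 2 * np.pi, size=len(spec.band_modulations))
    # fine integration grid; 100 points per mean interval is ample
    dt = min(1.0 / spec.fs, spec.mean_rri_ms / 1000.0 / 100.0)
    t = np.arange(0.0, spec.duration_s + dt, dt)
    rri_ms = np.full_like(t, spec.mean_rri_ms)
    for (f, a), phi in zip(spec.band_modulations, phases):
        rri_ms = rri_ms + a * np.sin(2 * np.pi * f * t + phi)
    rate = 1000.0 / rri_ms  # beats per second
    integral = np.concatenate(([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))))
    # half-integer crossings: first beat lands ~half an interval into the
    # record, so every ground-truth QRS is a detectable interior maximum
    n_beats = int(np.floor(integral[-1] + 0.5))
    targets = np.arange(n_beats, dtype=float) + 0.5
    beat_times = np.interp(targets, integral, t)
    # keep only beats whose template fits inside the record
    sigma_s = spec.qrs_width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    margin = 4.0 * sigma_s + 2.0 / spec.fs
    beat_times = beat_times[(beat_times >= margin) & (beat_times <= spec.duration_s - margin)]
    return beat_times, phases


def generate_ecg(spec: SyntheticECGSpec) -> tuple[ECGSignal, BeatSeries]:
    """Simulate an ECG waveform; also return the exact beats used as ground truth.

    Returns
    -------
    signal
        The waveform: Gaussian QRS bumps at the IPFM beat times, amplitude
        ``1 + sum of rwa modulations``, plus baseline wander and white noise.
    ground_truth
        The beat times (s) and beat amplitudes actually stamped into the
        waveform, for use as a detection/recovery oracle.
    """
    rng = np.random.default_rng(spec.seed)
    beat_times, _ = _beat_times_ipfm(spec, rng)

    rwa_phases = rng.uniform(0, 2 * np.pi, size=len(spec.rwa_modulations))
    amplitudes = np.ones_like(beat_times)
    for (f, a), phi in zip(spec.rwa_modulations, rwa_phases):
        amplitudes = amplitudes + a * np.sin(2 * np.pi * f * beat_times + phi)

    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    wave = np.zeros(n)
    # Gaussian QRS template: qrs_width_ms is the full width at half maximum
    sigma_s = spec.qrs_width_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half_w = int(np.ceil(4 * sigma_s * spec.fs))
    for bt, amp in zip(beat_times, amplitudes):
        center = bt * spec.fs
        lo = max(0, int(np.floor(center)) - half_w)
        hi = min(n, int(np.ceil(center)) + half_w + 1)
        idx = np.arange(lo, hi)
        wave[idx] += amp * np.exp(-0.5 * ((idx / spec.fs - bt) / sigma_s) ** 2)

    if spec.baseline_wander_amp:
        bw_phase = rng.uniform(0, 2 * np.pi)
        wave += spec.baseline_wander_amp * np.sin(
            2 * np.pi * spec.baseline_wander_freq_hz * t + bw_phase
        )
    if spec.noise_sd:
        wave += rng.normal(0.0, spec.noise_sd, size=n)

    signal = ECGSignal(samples=wave, fs=spec.fs)
    truth = BeatSeries(peak_times_s=beat_times, peak_amplitudes=amplitudes, fs_source=spec.fs)
    return signal, truth


def generate_cohort(spec: SyntheticCohortSpec) -> CohortTable:
    """Simulate a cohort table from the spec's known linear feature -> fRRI map.

    Features are independent Gaussians clipped at physiological floors (band
    powers and time-domain spreads at 0, mean RRI at 1 ms); the fetal target is
    ``intercept + weights . features + N(0, noise_sd)``, floored at 1 ms.
    Gestational age is uniform over ``ga_range_weeks``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, len(FEATURE_COLUMNS)
    X = rng.normal(spec.feature_means, spec.feature_sds, size=(n, p))
    floors = np.zeros(p)
    floors[FEATURE_COLUMNS.index("rri_ms")] = 1.0
    X = np.maximum(X, floors)
    frri = spec.intercept + X @ spec.weights + rng.normal(0.0, spec.noise_sd, size=n)
    frri = np.maximum(frri, 1.0)
    ga = rng.uniform(*spec.ga_range_weeks, size=n)
    width = len(str(n))
    records = [
        SubjectRecord(
            subject_id=f"S{i + 1:0{width}d}",
            ga_weeks=float(ga[i]),
            features=X[i],
            actual_frri_ms=float(frri[i]),
        )
        for i in range(n)
    ]
    return CohortTable(records)
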