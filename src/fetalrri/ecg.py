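"""ECG preprocessing and R-peak extraction.

The preprocessing chain mirrors standard non-invasive fetal/maternal ECG
practice: a 5 Hz zero-phase high-pass removes baseline drift, the signal is
normalized by its maximum (so the tallest R peak maps to 1), local maxima
above a height threshold and separated by a refractory distance are taken as
R peaks, and successive peak-time differences give the RR-interval series.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal as sps

from .types import (
    BeatSeries,
    DegenerateInputError,
    ECGSignal,
    InsufficientDataError,
    ParameterError,
    RRISeries,
)

__all__ = [
    "highpass_filter",
    "normalize",
    "detect_r_peaks",
    "beats_to_rri",
    "segment",
    "SegmentShortfall",
]


def highpass_filter(sig: ECGSignal, cutoff_hz: float = 5.0) -> ECGSignal:
    """Zero-phase 4th-order Butterworth high-pass.

    Applied forward-backward (``sosfiltfilt``) so R-peak times are not
    shifted. The default 5 Hz cutoff suppresses baseline wander and motion
    drift while leaving the QRS complex (10-40 Hz energy) intact.
    """
    nyq = sig.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(f"cutoff_hz must be in (0, {nyq}) for fs={sig.fs}")
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=sig.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples)
    return replace(sig, samples=filtered)


def normalize(sig: ECGSignal) -> ECGSignal:
    """Divide by the maximum amplitude so the highest R peak maps to 1.

    For a QRS-dominant lead after high-pass filtering the global maximum is
    the tallest R peak. If the largest absolute excursion is negative-going
    the lead is probably inverted; a warning is emitted and the (positive)
    maximum is still used.
    """
    peak = float(np.max(sig.samples))
    if peak <= 0 or not np.any(sig.samples != 0):
        raise DegenerateInputError("cannot normalize: signal has no positive excursion")
    if -float(np.min(sig.samples)) > peak:
        warnings.warn(
            "largest excursion is negative-going; lead may be inverted", stacklevel=2
        )
    return replace(sig, samples=sig.samples / peak)


def detect_r_peaks(
    sig: ECGSignal,
    min_rri_ms: float = 300.0,
    min_height: float = 0.4,
    refine_window_ms: float = 10.0,
) -> BeatSeries:
    """Find R peaks: local maxima above ``min_height`` separated by >= ``min_rri_ms``.

    Defaults suit a maternal lead (minimum RR 300 ms ~ 200 bpm ceiling); use
    ``min_rri_ms=200`` for fetal signals. The input should be filtered and
    normalized so that ``min_height`` is on the (0, 1] scale.

    Each detected maximum is refined to sub-sample precision by a
    least-squares quadratic fit over ``+/- refine_window_ms`` around it, which
    averages broadband noise across the peak instead of trusting a single
    sample's argmax; set ``refine_window_ms=0`` for raw sample positions.
    """
    if not min_rri_ms > 0:
        raise ParameterError("min_rri_ms must be positive")
    distance = max(1, int(round(min_rri_ms / 1000.0 * sig.fs)))
    idx, _ = sps.find_peaks(sig.samples, height=min_height, distance=distance)
    if idx.size == 0:
        warnings.warn("no R peaks detected", stacklevel=2)
    times = idx.astype(float)
    amps = sig.samples[idx].astype(float)
    w = int(round(refine_window_ms / 1000.0 * sig.fs))
    if w >= 2:
        for k, i in enumerate(idx):
            lo, hi = max(0, i - w), min(sig.samples.size, i + w + 1)
            x = np.arange(lo, hi, dtype=float) - i
            c = np.polynomial.polynomial.polyfit(x, sig.samples[lo:hi], 2)
            if c[2] < 0:  # concave: vertex is a maximum
                shift = -c[1] / (2 * c[2])
                if abs(shift) <= w:
                    times[k] = i + shift
                    amps[k] = c[0] + c[1] * shift + c[2] * shift**2
    # refinement can merge neighbours in pathological cases; keep order strict
    order = np.argsort(times)
    times, amps = times[order], amps[order]
    keep = (
        np.concatenate(([True], np.diff(times) > 0))
        if times.size
        else np.zeros(0, dtype=bool)
    )
    return BeatSeries(
        peak_times_s=sig.start_time_s + times[keep] / sig.fs,
        peak_amplitudes=amps[keep],
        fs_source=sig.fs,
    )


def beats_to_rri(beats: BeatSeries) -> RRISeries:
    """Successive R-peak time differences, in ms, timestamped at the later beat."""
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to form RR intervals")
    t = beats.peak_times_s
    return RRISeries(times_s=t[1:], intervals_ms=np.diff(t) * 1000.0)


class SegmentShortfall(UserWarning):
    """Fewer full analysis windows were available than requested."""


def segment(obj, window_s: float = 300.0, n_segments: int = 2) -> list:
    """Split a record into consecutive non-overlapping windows from its start.

    Works on :class:`ECGSignal` (sample windows) and :class:`BeatSeries`
    (beats falling in each half-open window ``[k*w, (k+1)*w)``). Each returned
    segment carries its absolute time offset. If the record is shorter than
    ``n_segments * window_s``, the available full segments are returned and a
    :class:`SegmentShortfall` warning reports the count — mirroring cohorts
    where only one 5-min window could be extracted for some subjects.
    """
    if window_s <= 0 or n_segments < 1:
        raise ParameterError("window_s must be positive and n_segments >= 1")
    if isinstance(obj, ECGSignal):
        total = obj.duration_s
    elif isinstance(obj, BeatSeries):
        total = float(obj.peak_times_s[-1] - obj.peak_times_s[0]) if len(obj) else 0.0
    else:
        raise TypeError(f"cannot segment object of type {type(obj).__name__}")

    available = int(np.floor(total / window_s + 1e-9))
    n_use = min(n_segments, available)
    if n_use < n_segments:
        warnings.warn(
            f"record supports only {available} full {window_s:.0f}-s segment(s); "
            f"{n_segments} requested",
            SegmentShortfall,
            stacklevel=2,
        )
    out = []
    for k in range(n_use):
        start = k * window_s
        if isinstance(obj, ECGSignal):
            i0 = int(round(start * obj.fs))
            i1 = int(round((start + window_s) * obj.fs))
            out.append(
                ECGSignal(
                    samples=obj.samples[i0:i1],
                    fs=obj.fs,
                    label=obj.label,
                    start_time_s=obj.start_time_s + start,
                )
            )
        else:
            t0 = obj.peak_times_s[0] + start
            mask = (obj.peak_times_s >= t0) & (obj.peak_times_s < t0 + window_s)
            out.append(
                BeatSeries(
                    peak_times_s=obj.peak_times_s[mask],
                    peak_amplitudes=obj.peak_amplitudes[mask],
                    fs_source=obj.fs_source,
                )
            )
    return out
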