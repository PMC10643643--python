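"""End-to-end stage wiring: waveforms -> features -> models -> evaluation.

These helpers chain the module-level operations in the order the study
pipeline runs them: high-pass filter (5 Hz), max-normalization, R-peak
detection, RR-interval formation, per-5-min-segment feature extraction,
cross-segment averaging, leave-one-out prediction and evaluation.
"""

from __future__ import annotations

import numpy as np

from .ecg import beats_to_rri, detect_r_peaks, highpass_filter, normalize, segment
from .evaluation import PredictionResult, evaluate_predictions
from .features import DEFAULT_BANDS, BandDefinition, assemble_subject, segment_features
from .models import ModelConfig, loo_cross_validate
from .types import CohortTable, ECGSignal, SubjectRecord

__all__ = ["process_ecg", "extract_subject", "run_loo_evaluation"]


def process_ecg(
    sig: ECGSignal,
    cutoff_hz: float = 5.0,
    min_rri_ms: float = 300.0,
    min_height: float = 0.4,
):
    """Filter, normalize and detect R peaks on one waveform; return the beats."""
    return detect_r_peaks(normalize(highpass_filter(sig, cutoff_hz)), min_rri_ms, min_height)


def extract_subject(
    maternal: ECGSignal,
    fetal: ECGSignal,
    age_years: float,
    weight_kg: float,
    subject_id: str = "S1",
    ga_weeks: float = 30.0,
    window_s: float = 300.0,
    n_segments: int = 2,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    maternal_min_rri_ms: float = 300.0,
    fetal_min_rri_ms: float = 200.0,
    min_height: float = 0.4,
) -> SubjectRecord:
    """Turn one maternal/fetal recording pair into a 13-feature subject record.

    Each channel is split into up to ``n_segments`` windows of ``window_s``;
    maternal windows yield the 11 ECG-derived features, fetal windows the
    mean fetal RRI, and :func:`assemble_subject` averages across windows.
    """
    m_segments = segment(maternal, window_s, n_segments)
    f_segments = segment(fetal, window_s, n_segments)
    n_use = min(len(m_segments), len(f_segments))
    m_feats = []
    f_means = []
    for k in range(n_use):
        m_beats = process_ecg(m_segments[k], min_rri_ms=maternal_min_rri_ms, min_height=min_height)
        f_beats = process_ecg(f_segments[k], min_rri_ms=fetal_min_rri_ms, min_height=min_height)
        m_feats.append(segment_features(m_beats, bands))
        f_means.append(float(np.mean(beats_to_rri(f_beats).intervals_ms)))
    return assemble_subject(m_feats, f_means, age_years, weight_kg, subject_id, ga_weeks)


def run_loo_evaluation(cohort: CohortTable, model_cfg: ModelConfig) -> PredictionResult:
    """Leave-one-out predictions for every subject plus the full evaluation."""
    preds = loo_cross_validate(model_cfg, cohort)
    return evaluate_predictions(cohort.subject_ids, cohort.ga_weeks, cohort.targets(), preds)
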