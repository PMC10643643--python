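"""Preprocessing and R-peak extraction against generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalrri import (
    BeatSeries,
    DegenerateInputError,
    ECGSignal,
    InsufficientDataError,
    ParameterError,
    SyntheticECGSpec,
    beats_to_rri,
    detect_r_peaks,
    generate_ecg,
    highpass_filter,
    normalize,
    segment,
)
from fetalrri.ecg import SegmentShortfall


def _sine(freq, fs=1000.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return ECGSignal(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestHighpass:
    def test_dc_rejected(self):
        sig = ECGSignal(samples=np.full(5000, 3.0), fs=1000.0)
        out = highpass_filter(sig)
        assert np.max(np.abs(out.samples)) < 1e-6 * 3.0

    def test_baseline_band_attenuated(self):
        out = highpass_filter(_sine(0.3, dur=20.0))
        mid = slice(2000, -2000)  # avoid filtfilt edge transients
        assert np.std(out.samples[mid]) < 0.1 * np.std(_sine(0.3, dur=20.0).samples[mid])

    def test_qrs_band_passed(self):
        out = highpass_filter(_sine(15.0))
        assert np.std(out.samples) > 0.9 * np.std(_sine(15.0).samples)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            highpass_filter(_sine(1.0, fs=100.0), cutoff_hz=60.0)


class TestNormalize:
    def test_max_becomes_one_and_invertible(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 1, 2000) + 2.5 * np.exp(-np.linspace(-3, 3, 2000) ** 2)
        sig = ECGSignal(samples=raw, fs=500.0)
        out = normalize(sig)
        assert np.max(out.samples) == pytest.approx(1.0)
        np.testing.assert_allclose(out.samples * np.max(raw), raw, rtol=1e-12)

    def test_idempotent(self):
        sig = normalize(_sine(5.0))
        again = normalize(sig)
        np.testing.assert_array_equal(sig.samples, again.samples)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize(ECGSignal(samples=np.zeros(100), fs=100.0))

    def test_inverted_lead_warns(self):
        t = np.arange(1000) / 1000.0
        sig = ECGSignal(samples=0.2 * np.sin(2 * np.pi * 3 * t) - 2.0 * np.exp(-((t - 0.5) ** 2) / 1e-4), fs=1000.0)
        with pytest.warns(UserWarning, match="negative-going"):
            normalize(ECGSignal(samples=sig.samples - sig.samples.mean(), fs=1000.0))


class TestDetect:
    def test_flat_signal_yields_no_peaks(self):
        with pytest.warns(UserWarning, match="no R peaks"):
            beats = detect_r_peaks(ECGSignal(samples=np.zeros(1000), fs=1000.0))
        assert len(beats) == 0

    def test_noise_free_recovery_within_one_sample(self, clean_ecg):
        sig, truth = clean_ecg
        beats = detect_r_peaks(normalize(highpass_filter(sig)))
        assert len(beats) == len(truth)
        err_s = np.abs(beats.peak_times_s - truth.peak_times_s)
        assert np.max(err_s) <= 1.0 / sig.fs

    def test_noisy_sensitivity(self, noisy_ecg):
        sig, truth = noisy_ecg
        beats = detect_r_peaks(normalize(highpass_filter(sig)))
        d = np.abs(beats.peak_times_s[:, None] - truth.peak_times_s[None, :]).min(axis=0)
        assert np.mean(d <= 0.005) >= 0.99

    def test_translation_equivariance(self):
        spec = SyntheticECGSpec(duration_s=40, mean_rri_ms=750.0,
                                band_modulations=((0.1, 15.0),), seed=21)
        sig, _ = generate_ecg(spec)
        base = detect_r_peaks(normalize(highpass_filter(sig)))
        shift = 2.0  # whole seconds keep the sample grid aligned
        shifted = ECGSignal(samples=sig.samples, fs=sig.fs, start_time_s=shift)
        moved = detect_r_peaks(normalize(highpass_filter(shifted)))
        np.testing.assert_allclose(moved.peak_times_s, base.peak_times_s + shift, atol=1e-9)


class TestRRI:
    def test_simple_differences(self):
        beats = BeatSeries(np.array([0.0, 0.8, 1.6]), np.ones(3), 1000.0)
        rri = beats_to_rri(beats)
        np.testing.assert_allclose(rri.intervals_ms, [800.0, 800.0])
        np.testing.assert_allclose(rri.times_s, [0.8, 1.6])
        single = beats_to_rri(BeatSeries(np.array([0.0, 0.763]), np.ones(2), 1000.0))
        np.testing.assert_allclose(single.intervals_ms, [763.0])

    def test_too_few_beats(self):
        with pytest.raises(InsufficientDataError):
            beats_to_rri(BeatSeries(np.array([0.5]), np.ones(1), 1000.0))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.2, max_value=2.0), min_size=2, max_size=60))
    def test_telescoping_identity(self, gaps):
        times = np.concatenate(([0.0], np.cumsum(gaps)))
        beats = BeatSeries(times, np.ones_like(times), 1000.0)
        rri = beats_to_rri(beats)
        assert times[0] + rri.intervals_ms.sum() / 1000.0 == pytest.approx(times[-1])

    def test_noise_free_rri_recovery_within_2ms(self, clean_ecg):
        sig, truth = clean_ecg
        beats = detect_r_peaks(normalize(highpass_filter(sig)))
        got = beats_to_rri(beats).intervals_ms
        want = np.diff(truth.peak_times_s) * 1000.0
        assert got.size == want.size
        np.testing.assert_allclose(got, want, atol=2.0)


class TestSegment:
    def test_partition_of_600s(self):
        sig = ECGSignal(samples=np.zeros(600_000), fs=1000.0)
        segs = segment(sig, 300.0, 2)
        assert [s.start_time_s for s in segs] == [0.0, 300.0]
        assert all(s.samples.size == 300_000 for s in segs)

    def test_short_record_reports_shortfall(self):
        sig = ECGSignal(samples=np.zeros(320_000), fs=1000.0)
        with pytest.warns(SegmentShortfall, match="only 1"):
            segs = segment(sig, 300.0, 2)
        assert len(segs) == 1

    def test_20min_record_uses_first_two_windows(self):
        sig = ECGSignal(samples=np.zeros(1_200_000), fs=1000.0)
        segs = segment(sig, 300.0, 2)
        assert len(segs) == 2
        assert segs[1].start_time_s == 300.0

    def test_beats_segmented_by_halfopen_windows(self):
        times = np.arange(0.0, 650.0, 0.8)
        beats = BeatSeries(times, np.ones_like(times), 1000.0)
        segs = segment(beats, 300.0, 2)
        assert len(segs) == 2
        assert segs[0].peak_times_s.max() < 300.0
        assert segs[1].peak_times_s.min() >= 300.0
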