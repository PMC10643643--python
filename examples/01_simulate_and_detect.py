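"""Simulate a maternal ECG and recover its beats.

Builds a 5-min, 1 kHz maternal-like waveform whose RR interval carries an LF
(0.1 Hz) and an HF/respiratory (0.3 Hz) modulation, runs the detection chain
(5 Hz high-pass -> max-normalization -> peak picking), and compares the
detected beats with the generator's ground truth.
"""

import numpy as np

from fetalrri import SyntheticECGSpec, generate_ecg, process_ecg, beats_to_rri

spec = SyntheticECGSpec(
    duration_s=300.0,
    fs=1000.0,
    mean_rri_ms=763.0,
    band_modulations=((0.1, 20.0), (0.3, 12.0)),
    rwa_modulations=((0.3, 0.05),),
    noise_sd=0.03,
    baseline_wander_amp=0.1,
    seed=1,
)
signal, truth = generate_ecg(spec)
beats = process_ecg(signal)

d = np.abs(beats.peak_times_s[:, None] - truth.peak_times_s[None, :]).min(axis=0)
rri = beats_to_rri(beats)

print(f"ground-truth beats : {len(truth)}")
print(f"detected beats     : {len(beats)}")
print(f"sensitivity @5 ms  : {100 * np.mean(d <= 0.005):.1f} %")
print(f"mean RRI           : {rri.intervals_ms.mean():.1f} ms (spec: {spec.mean_rri_ms})")
print(f"SDNN               : {np.std(rri.intervals_ms, ddof=1):.1f} ms")
# Sensitivity near 100 % and a mean RRI near the spec value show the detector
# recovers the simulated rhythm; SDNN reflects the injected LF+HF modulation.
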