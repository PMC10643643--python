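import numpy as np
import pytest

from fetalrri import (
    ModelConfig,
    SyntheticCohortSpec,
    SyntheticECGSpec,
    generate_cohort,
    generate_ecg,
)


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free 300-s maternal-like recording with LF + HF RRI modulation."""
    spec = SyntheticECGSpec(
        duration_s=300.0,
        fs=1000.0,
        mean_rri_ms=763.0,
        band_modulations=((0.1, 20.0), (0.3, 12.0)),
        rwa_modulations=((0.3, 0.05),),
        noise_sd=0.0,
        seed=11,
    )
    return generate_ecg(spec)


@pytest.fixture(scope="session")
def noisy_ecg():
    spec = SyntheticECGSpec(
        duration_s=300.0,
        fs=1000.0,
        mean_rri_ms=763.0,
        band_modulations=((0.1, 20.0),),
        noise_sd=0.05,
        baseline_wander_amp=0.1,
        seed=12,
    )
    return generate_ecg(spec)


@pytest.fixture(scope="session")
def linear_cohort():
    """150 subjects from the default linear mapping, 10 ms target noise."""
    return generate_cohort(SyntheticCohortSpec(n_subjects=150, noise_sd=10.0, seed=5))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(SyntheticCohortSpec(n_subjects=60, noise_sd=0.0, seed=6))


@pytest.fixture()
def svr_config():
    return ModelConfig(kind="svr")


@pytest.fixture()
def rf_config():
    return ModelConfig(kind="rf", seed=7)
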