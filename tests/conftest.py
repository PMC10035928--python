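import numpy as np
import pytest

from spinetopo.synthetic import (
    GeneratorConfig,
    SubjectDemographics,
    generate_cohort,
)


@pytest.fixture()
def subject():
    return SubjectDemographics(
        subject_id="S001", gender="F", age=24, height_m=1.70, weight_kg=65.0
    )


@pytest.fixture()
def quiet_config():
    """Noise-free generator: every stochastic term switched off."""
    return GeneratorConfig(
        n_subjects=4,
        seed=0,
        adipose_noise_sd_mm=0.0,
        lateral_bias_sd_mm=0.0,
        posture_amplitude_lateral_mm=0.0,
        posture_amplitude_ap_mm=0.0,
        reposition_noise_sd_mm=0.0,
        observer_noise_sd_mm=0.0,
        reliability_subjects=(0,),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default 20-subject cohort shared across read-only tests."""
    cfg = GeneratorConfig(n_subjects=20, seed=11, reliability_subjects=(2,))
    demographics, landmark_sets = generate_cohort(cfg)
    return cfg, demographics, landmark_sets


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
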