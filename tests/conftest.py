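import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specdx
from specdx.model import ModelConfig
from specdx.study import seeded_replication_metrics
from specdx.synthetic import GeneratorConfig, sample_specimen

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """Noise-free, jitter-free configuration with admixture pinned to 0."""
    return dataclasses.replace(
        GeneratorConfig(),
        noise_sd=0.0,
        specimen_effect_sd=0.0,
        background_sd=0.0,
        amplitude_jitter_sd=0.0,
        focal_mixing={c: 0.0 for c in specdx.GeneratorConfig().focal_mixing},
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def iac_specimen(default_config) -> specdx.Specimen:
    return sample_specimen(
        default_config, specdx.SpectralClass.IAC, np.random.default_rng(7), "S-IAC"
    )


@pytest.fixture(scope="session")
def small_model_config() -> ModelConfig:
    """Reduced training budget for tests that only need a rough fit."""
    return ModelConfig(epochs=8, conv_channels=(8, 16), dense_width=32)


@pytest.fixture(scope="session")
def pipeline_runs() -> list[dict]:
    """Five seeded study-scale pipeline replications (shared across tests).

    Each run: default 116-specimen modeling cohort, within-specimen 9:1
    split, default CNN, plus a 200-specimen validation cohort with
    simulated FS calls scored at the majority threshold.
    """
    config = specdx.StudyConfig()
    return [
        seeded_replication_metrics(config, seed=seed, validation_n=200)
        for seed in range(1, 6)
    ]
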