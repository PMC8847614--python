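import numpy as np
import pytest

from gazesurprise.simulate import GeneratorConfig, generate_subject


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """Noise-free, blink-free generator: detection ground truth is exact."""
    return GeneratorConfig(seed=7, n_subjects=2, trials_per_condition=6,
                           gaze_noise_sd=0.0, gaze_jitter_sd=0.0,
                           blink_rate=0.0)


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    return generate_subject(clean_config, 0)


@pytest.fixture(scope="session")
def default_small_config() -> GeneratorConfig:
    """Default noise levels, reduced cohort for fast end-to-end checks."""
    return GeneratorConfig(seed=13, n_subjects=4, trials_per_condition=8)


def flat_trace(n: int = 2000, dt: float = 2.0):
    """A noise-free fixation trace at the origin."""
    t = np.arange(n) * dt
    return t, np.zeros(n), np.zeros(n)
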