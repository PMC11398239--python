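import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

from chestmorph.phantom import PhantomConfig, generate_sequence  # noqa: E402


@pytest.fixture(scope="session")
def phantom_short():
    """A 2 s default-condition phantom: (config, sequence, ground truth)."""
    config = PhantomConfig(duration=2.0, seed=3)
    sequence, gt = generate_sequence(config)
    return config, sequence, gt


@pytest.fixture(scope="session")
def phantom_clean():
    """A noise- and jitter-free 8 s phantom for exactness checks."""
    config = PhantomConfig(duration=8.0, seed=4, noise_sigma=0.0,
                           period_jitter=0.0, amplitude_jitter=0.0,
                           baseline_jitter=0.0)
    sequence, gt = generate_sequence(config)
    return config, sequence, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
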