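import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small 6-channel dataset with 2 planted channels, reused across tests."""
    from bwhpat.synthetic_data import SynthConfig, generate_dataset

    cfg = SynthConfig(n_subjects=9, n_channels=6, record_seconds=8.0,
                      discriminative_channels=(1, 4), effect_size=3.0, seed=5)
    return generate_dataset(cfg)
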