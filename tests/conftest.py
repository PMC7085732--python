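import numpy as np
import pytest

from fallcnn import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard separable study collection: 60 ADLs + 40 falls, 50 Hz, 10 s."""
    traces, manifest = generate_dataset(SyntheticConfig(seed=1))
    return traces, manifest


@pytest.fixture(scope="session")
def small_dataset():
    """A fast low-rate collection for benchmark plumbing tests."""
    cfg = SyntheticConfig(fs=25.0, duration_s=6.0, n_adl=7, n_fall=7, seed=11)
    traces, manifest = generate_dataset(cfg)
    return traces, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
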