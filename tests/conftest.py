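import numpy as np
import pytest
from hypothesis import settings

import meghfo as m

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-size labeled dataset (T=400, 30+30, SNR 3), preprocessed."""
    ds = m.simulate_dataset(30, 30, T=400, seed=42)
    return m.preprocess_dataset(ds)


@pytest.fixture(scope="session")
def tiny_config():
    """A transformer configuration small enough for exhaustive checks."""
    return m.ModelConfig(n_layers=1, n_heads=2, d_model=8, frame_width=10,
                         ffn_width=16, dropout_rate=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
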