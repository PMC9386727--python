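import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small architecture used wherever the test only needs a working model."""
    from proteinlm import ModelConfig
    return ModelConfig(d_local=8, d_global=16, n_blocks=2, n_heads=2, d_key=4,
                       n_annotations=6)
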