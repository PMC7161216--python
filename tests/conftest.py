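import numpy as np
import pytest

from lapnet.policy import PolicyModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model():
    """A float64 model with perturbed final layer so gradients are nonzero."""
    model = PolicyModel(n_blocks=3, n_channels=8, seed=3, normalization=1.0)
    gen = np.random.default_rng(42)
    last = model.layers[-1].params["weight"]
    last += gen.normal(0.0, 0.1, last.shape)
    return model
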