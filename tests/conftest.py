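import numpy as np
import pytest

from sparsernn import SyntheticTaskSpec, make_task


@pytest.fixture(scope="session")
def default_task():
    """The default synthetic task (10 classes, 28x28, noise sd 0.1)."""
    return make_task(SyntheticTaskSpec())


@pytest.fixture(scope="session")
def tiny_task():
    """A fast low-dimensional task for training-loop tests."""
    spec = SyntheticTaskSpec(
        n_classes=4, seq_len=8, input_dim=6, n_train=80, n_test=40,
        noise_sd=0.05, jitter=0, seed=7,
    )
    return make_task(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
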