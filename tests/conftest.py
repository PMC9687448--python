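import numpy as np
import pytest

from octovessel.phantom import PhantomParams, generate_pullback


@pytest.fixture(scope="session")
def small_phantom():
    """A small desk-preset phantom pullback shared by read-only tests."""
    params = PhantomParams.desk(seed=7, n_frames=10)
    pullback, labels, scene = generate_pullback(params)
    return params, pullback, labels, scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
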