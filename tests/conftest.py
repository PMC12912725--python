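import numpy as np
import pytest

from wormalign import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def phantom():
    """A small worm-like phantom shared across tests."""
    return synthetic.make_phantom(
        synthetic.PhantomSpec(dims=(64, 32, 16), n_cells=40, seed=7)
    )


@pytest.fixture(scope="session")
def bent_pair(phantom):
    return synthetic.make_bent_pair(
        phantom, synthetic.BendSpec(amplitude=4.0, wavelength=96.0, phase=0.9)
    )
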