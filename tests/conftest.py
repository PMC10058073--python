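import numpy as np
import pytest

from octprofiler.phantom import PhantomConfig, make_phantom, noiseless


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter phantom shared across tests (seed fixed)."""
    return make_phantom(PhantomConfig(seed=1234))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Speckle-free, unquantized phantom: columns lie exactly in the
    Beer-Lambert model class."""
    return make_phantom(noiseless(PhantomConfig(seed=1234)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230625)
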