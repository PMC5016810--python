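import numpy as np
import pytest

from patchchain.epdm import ChainParams
from patchchain.landscape import LatticeConfig, generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20160909)


@pytest.fixture(scope="session")
def params2():
    """Symmetric prey-predator rates used throughout: c=1, e=0.05, mu=0.025."""
    return ChainParams.symmetric(2)


@pytest.fixture(scope="session")
def params3():
    return ChainParams.symmetric(3)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(LatticeConfig(30), 0.5, 0.6, seed=7)
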