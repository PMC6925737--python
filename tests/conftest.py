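import numpy as np
import pytest

from ciliaflow.lattice import LatticeSpec


@pytest.fixture(scope="session")
def unit_spec():
    """Small unit lattice used by most core tests."""
    return LatticeSpec(16, 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
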