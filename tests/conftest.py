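import numpy as np
import pytest

from faogen import HexGrid, OrientationBank


@pytest.fixture(scope="session")
def grid():
    """The default 635-location grid, shared across tests (immutable)."""
    return HexGrid()


@pytest.fixture(scope="session")
def bank():
    return OrientationBank()


@pytest.fixture
def rng():
    return np.random.default_rng(20190411)
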