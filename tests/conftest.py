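import numpy as np
import pytest
from hypothesis import settings

from geofold import BeadChain, ContactNetwork

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def straight3():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    return BeadChain(pos, np.full(3, 0.5))


@pytest.fixture
def unit_square_chain():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0], [0.0, 1, 0]])
    return BeadChain(pos, np.full(4, 0.5))


@pytest.fixture
def path4():
    return ContactNetwork(4, {(0, 1), (1, 2), (2, 3)})


@pytest.fixture
def complete4():
    return ContactNetwork(4, {(i, j) for i in range(4) for j in range(i + 1, 4)})
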