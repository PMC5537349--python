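import numpy as np
import pytest

from coextnet import InteractionNetwork, generate_community, preset


@pytest.fixture
def toy22():
    """2x2 network with visits [[3,1],[0,4]] — hand-checkable throughout."""
    return InteractionNetwork(("A", "B"), ("x", "y"), np.array([[3.0, 1.0], [0.0, 4.0]]))


@pytest.fixture
def toy22_dep():
    return {"A": 0.5, "B": 1.0}


@pytest.fixture
def toy_equal():
    """One plant, two equal-weight partners, IPD 0.5 (2-event outcome tree)."""
    net = InteractionNetwork(("A",), ("x", "y"), np.array([[1.0, 1.0]]))
    return net, {"A": 0.5}


@pytest.fixture(scope="session")
def sb_community():
    """Synthetic community at the larger (SB) preset scale."""
    return generate_community(preset("SB", seed=11))


@pytest.fixture(scope="session")
def pm_community():
    """Synthetic community at the smaller (PM) preset scale."""
    return generate_community(preset("PM", seed=13))
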