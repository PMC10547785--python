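import numpy as np
import pytest

from sucpipe.stoichiometry import build_default_network
from sucpipe.tea import BiorefineryScenario


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def pilot_scenario():
    """Pilot-scale batch fermentation performance point."""
    return BiorefineryScenario(yield_=0.473, titer=63.1, productivity=0.657)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
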