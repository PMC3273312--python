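import numpy as np
import pytest

from lesionnet import generate_graph, make_fixture


@pytest.fixture(scope="session")
def chain3():
    return make_fixture("chain3")


@pytest.fixture(scope="session")
def star5():
    return make_fixture("star5")


@pytest.fixture(scope="session")
def handplaced5():
    return make_fixture("handplaced5")


@pytest.fixture(scope="session")
def dense20():
    return make_fixture("dense20")


@pytest.fixture(scope="session")
def rgg400():
    """One medium random geometric graph in the reference configuration."""
    return generate_graph(400, 0.2, np.random.SeedSequence([99, 0]))
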