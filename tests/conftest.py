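import numpy as np
import pytest

import hypersis as hs

GAMMA = 2.0


@pytest.fixture(scope="session")
def pl4():
    """Power law r=4 on 67..1000 — the workhorse heterogeneous distribution."""
    return hs.make_powerlaw(4.0, 67, 1000)


@pytest.fixture(scope="session")
def pl3():
    return hs.make_powerlaw(3.0, 53, 1000)


@pytest.fixture(scope="session")
def unif():
    return hs.make_uniform(51, 149)


@pytest.fixture(scope="session")
def reg100():
    return hs.make_regular(100)


@pytest.fixture(scope="session")
def toy_triangle():
    return hs.build_fixture("toy-triangle")


@pytest.fixture(scope="session")
def regular_links():
    """k=100 regular links-only graph, N=2000, exact degrees via stub matching."""
    return hs.build_fixture("regular-links", seed=7)
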