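import pytest

from opanet.cli import fixture_network


@pytest.fixture
def pair():
    return fixture_network("pair")


@pytest.fixture
def path3():
    """Path on 3 nodes with the center at id 0 (degrees 2, 1, 1)."""
    return fixture_network("path3")


@pytest.fixture
def star4():
    """Star with center 0 and three leaves (degrees 3, 1, 1, 1)."""
    return fixture_network("star4")


@pytest.fixture
def triangle():
    return fixture_network("triangle")


@pytest.fixture
def k4():
    return fixture_network("k4")
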