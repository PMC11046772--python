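import pytest

from bisdl.examples_fixtures import (
    bacterial_consortium,
    plasmid_transfer,
    rgb_morphogen,
    water_reaction,
)


@pytest.fixture
def water_fixture():
    return water_reaction()


@pytest.fixture
def consortium_fixture():
    return bacterial_consortium()


@pytest.fixture
def rgb_fixture():
    return rgb_morphogen()


@pytest.fixture
def plasmid_fixture():
    return plasmid_transfer()


@pytest.fixture
def water_model(water_fixture):
    return water_fixture.model()


@pytest.fixture
def consortium_model(consortium_fixture):
    return consortium_fixture.model()
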