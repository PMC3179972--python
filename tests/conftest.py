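import io

import pytest
from hypothesis import settings

from orthomerge import fixtures as fx
from orthomerge import go_semsim as gs

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SEED = 1234


@pytest.fixture(scope="session")
def spec():
    return fx.WorldSpec(seed=SEED)


@pytest.fixture(scope="session")
def world(spec):
    return fx.generate_orthology_world(spec)


@pytest.fixture(scope="session")
def tool_pair_sets(world):
    return world.tool_pair_sets()


@pytest.fixture(scope="session")
def go_fixture(spec):
    return fx.generate_go_fixture(spec)


@pytest.fixture(scope="session")
def dag(go_fixture):
    return gs.load_obo(io.StringIO(go_fixture.obo_text))


@pytest.fixture(scope="session")
def annotations(go_fixture, dag):
    return gs.load_gaf(io.StringIO(go_fixture.gaf_text), dag)


@pytest.fixture(scope="session")
def term_ic(annotations, dag):
    return gs.compute_ic(annotations, dag)


@pytest.fixture(scope="session")
def sequence_fixture(spec):
    return fx.generate_sequence_fixture(spec)


@pytest.fixture(scope="session")
def disease_fixture(spec):
    return fx.generate_disease_fixture(spec)
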