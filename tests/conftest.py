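import pytest

from integrinsim import bngl, fixtures
from integrinsim.engine import generate_network
from integrinsim.model import build_default_model
from integrinsim import simulate as sim


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def default_network(default_model):
    return default_model.generate_network()


@pytest.fixture(scope="session")
def default_system(default_model, default_network):
    return sim.compile_odes(default_network, default_model.compartment_volumes)


@pytest.fixture(scope="session")
def observable_matrix(default_model, default_network):
    return default_model.observable_matrix(default_network)


@pytest.fixture(scope="session", params=fixtures.FIXTURE_IDS)
def toy(request):
    """Each toy fixture parsed and expanded into its network."""
    fx = fixtures.generate_toy_fixture(request.param)
    parsed = bngl.parse_model(fx.model_text)
    net = generate_network(
        parsed.molecules, parsed.rules, [s.species for s in parsed.seeds]
    )
    return fx, parsed, net
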