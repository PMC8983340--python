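import pytest

from bsarank import RunConfig, ebov_fixture, ebov_similarity_provider, table1_fixture


@pytest.fixture
def ebov_bundle():
    return ebov_fixture()


@pytest.fixture
def ebov_provider():
    return ebov_similarity_provider()


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def table1():
    return table1_fixture()


@pytest.fixture
def suitability_by_name(config):
    """Route-suitability map as plain strings, for the rules oracle."""
    return {
        system.value: {r.value for r in routes}
        for system, routes in config.route_suitability.items()
    }
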