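import pytest
from hypothesis import HealthCheck, settings

from seponto.el_reasoner import classify
from seponto.trunk_model import build_liver_exemplar, build_trunk_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trunk():
    return build_trunk_model()


@pytest.fixture(scope="session")
def trunk_taxonomy(trunk):
    return classify(trunk.ontology)


@pytest.fixture(scope="session")
def liver():
    return build_liver_exemplar()


@pytest.fixture(scope="session")
def liver_taxonomy(liver):
    return classify(liver.ontology)
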