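import pytest
from hypothesis import settings

from lvnc_triage import make_paper_fixture
from lvnc_triage.consensus import classify_catalog
from lvnc_triage.population import lookup_presence

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return make_paper_fixture()


@pytest.fixture(scope="session")
def catalog(bundle):
    return bundle.catalog


@pytest.fixture(scope="session")
def presences(bundle):
    esp = lookup_presence(bundle.catalog, bundle.esp_store, "ESP")
    exac = lookup_presence(bundle.catalog, bundle.exac_store, "ExAC")
    return esp, exac


@pytest.fixture(scope="session")
def classifications(bundle):
    return classify_catalog(bundle.catalog)
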