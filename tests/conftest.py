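import pytest

from trackmeta.fixtures import make_fixture_registries, make_valid_document
from trackmeta.validator import DocumentValidator


@pytest.fixture(scope="session")
def registries():
    return make_fixture_registries()


@pytest.fixture(scope="session")
def validator(registries):
    return DocumentValidator(registries)


@pytest.fixture()
def valid_doc():
    return make_valid_document(42)
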