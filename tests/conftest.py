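import pytest

from gogroups import fixtures


@pytest.fixture(scope="session")
def cannabinoid_ontology():
    return fixtures.toy_cannabinoid_ontology()


@pytest.fixture(scope="session")
def pattern_ontology():
    return fixtures.toy_pattern_ontology()
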