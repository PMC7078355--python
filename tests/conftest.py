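import pytest

from hpraudit import fixtures


@pytest.fixture(scope="session")
def sheep():
    return fixtures.sheep_template()


@pytest.fixture(scope="session")
def table2():
    """(protocol fragment, audit) for the worked single-chapter skinning example."""
    return fixtures.table2_audit()
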