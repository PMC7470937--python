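import pytest

from pairdex import fixtures as fx


@pytest.fixture(scope="session")
def catalog_entries():
    """All 47 constructed catalog fixtures, built once per session."""
    return fx.catalog()


@pytest.fixture(scope="session")
def catalog_by_name(catalog_entries):
    return {e.expected.text: e for e in catalog_entries}
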