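import pytest

from rfamide import catalog


@pytest.fixture(scope="session")
def peptides():
    return catalog.load_peptides()


@pytest.fixture(scope="session")
def precursors():
    return catalog.load_precursors()


@pytest.fixture(scope="session")
def peptide_by_id(peptides):
    return {r.peptide_id: r for r in peptides}
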