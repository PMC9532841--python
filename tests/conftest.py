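import pytest

from latamp import study_peptide
from latamp.design import extract_region


@pytest.fixture(scope="session")
def ltc3a():
    return study_peptide("Ltc-3a")


@pytest.fixture(scope="session")
def map1():
    return study_peptide("Lt-MAP1")


@pytest.fixture(scope="session")
def map2():
    return study_peptide("Lt-MAP2")


@pytest.fixture(scope="session")
def map3():
    return study_peptide("Lt-MAP3")


@pytest.fixture(scope="session")
def fragment(ltc3a):
    """The parent helix core, parent positions 5-17 (MAKKLKEYMEKLK)."""
    return extract_region(ltc3a, 5, 17)
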