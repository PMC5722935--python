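import pytest

from pepflux import (
    find_cleavage_sites,
    load_reference_table,
    load_rule_set,
    mature_bsa,
)
from pepflux.physchem import default_pka_table
from pepflux.sequences import ProteinSequence


@pytest.fixture(scope="session")
def bsa():
    return mature_bsa()


@pytest.fixture(scope="session")
def pepsin():
    return load_rule_set("pepsin-ph2")


@pytest.fixture(scope="session")
def pepsin_ph13():
    return load_rule_set("pepsin-ph1.3")


@pytest.fixture(scope="session")
def bsa_map(bsa, pepsin):
    return find_cleavage_sites(bsa, pepsin)


@pytest.fixture(scope="session")
def reference():
    """The 43 annotated peptides of the bundled BSA peptic reference table."""
    return load_reference_table()


@pytest.fixture(scope="session")
def pka():
    return default_pka_table()


def make_protein(residues: str) -> ProteinSequence:
    return ProteinSequence(identifier="test", residues=residues)


@pytest.fixture
def protein_factory():
    return make_protein
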