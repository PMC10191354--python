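import pytest

from phenokit.generate import invalid_fixture_trees, marfan_phenopacket
from phenokit.ontology import make_fixture_ontology
from phenokit.validation import (
    HpoAncestryValidator,
    HpoOrganSystemValidator,
    HpoPhenotypeValidator,
    MetaDataValidator,
    ValidationWorkflowRunner,
    rare_disease_validator,
)


@pytest.fixture(scope="session")
def graph():
    return make_fixture_ontology()


@pytest.fixture(scope="session")
def marfan():
    return marfan_phenopacket()


@pytest.fixture(scope="session")
def fixtures():
    return invalid_fixture_trees()


@pytest.fixture()
def full_runner(graph):
    """Base + metadata + rare-disease schema + all HPO validators (eye)."""
    return ValidationWorkflowRunner(
        [
            MetaDataValidator(),
            rare_disease_validator(),
            HpoPhenotypeValidator(graph),
            HpoAncestryValidator(graph),
            HpoOrganSystemValidator(graph, ["HP:0000478"]),
        ]
    )
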