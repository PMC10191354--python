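"""Validation workflow: error surface, semantic validators, contracts.

The expected message strings for the nine named invalid fixtures are the
frozen templates of the validators; the ancestry validator is additionally
cross-checked against a brute-force all-pairs oracle.
"""

import random

import pytest

from phenokit.generate import marfan_phenopacket, random_documents
from phenokit.model import OntologyClass, PhenotypicFeature, serialize_top_level
from phenokit.validation import (
    HpoAncestryValidator,
    HpoOrganSystemValidator,
    HpoPhenotypeValidator,
    JsonSchemaValidator,
    Level,
    MetaDataValidator,
    ValidationWorkflowRunner,
    rare_disease_validator,
)

# fixture name -> (extra validators needed, expected messages in order)
DESIGNATED = {
    "missing-fields": (
        "base",
        [
            "'id' is missing but it is required",
            "'subject.id' is missing but it is required",
            "'phenotypicFeatures[0].type.label' is missing but it is required",
        ],
    ),
    "missing-resources": (
        "metadata",
        ["No ontology corresponding to ID 'NCBITaxon:9606' found in MetaData"],
    ),
    "marfan.no-subject": ("custom", ["'Subject' is missing but it is required"]),
    "marfan.no-phenotype": (
        "custom",
        ["'phenotypicFeatures' is missing but it is required"],
    ),
    "marfan.not-hpo": (
        "custom",
        [r"'phenotypicFeatures[0].type.id' does not match the regex pattern ^HP:\d{7}$"],
    ),
    "marfan.no-time-at-last-encounter": (
        "custom",
        ["'subject.timeAtLastEncounter' is missing but it is required"],
    ),
    "marfan.obsolete-term": (
        "hpo-primary",
        [
            "Using obsolete id (HP:0002631) instead of current primary id "
            "(HP:0002616) in id-C"
        ],
    ),
    "marfan.annotation-propagation-rule": (
        "hpo-ancestry",
        [
            "Phenotypic features of id-C must not contain both an observed term "
            "(Aortic root aneurysm, HP:0002616) and an observed ancestor "
            "(Aortic aneurysm, HP:0004942)"
        ],
    ),
    "marfan.missing-eye-annotation": (
        "hpo-organ",
        ["Missing annotation for Abnormality of the eye [HP:0000478] in id-C"],
    ),
}


def _designated_runner(stack: str, graph) -> ValidationWorkflowRunner:
    extras = {
        "base": [],
        "metadata": [MetaDataValidator()],
        "custom": [rare_disease_validator()],
        "hpo-primary": [HpoPhenotypeValidator(graph)],
        "hpo-ancestry": [HpoAncestryValidator(graph)],
        "hpo-organ": [HpoOrganSystemValidator(graph, ["HP:0000478"])],
    }[stack]
    return ValidationWorkflowRunner(extras)


@pytest.mark.parametrize("name", list(DESIGNATED))
def test_invalid_fixture_emits_exact_messages(name, fixtures, graph):
    stack, expected = DESIGNATED[name]
    results = _designated_runner(stack, graph).run(fixtures[name])
    assert [r.message for r in results.results] == expected


def test_valid_marfan_passes_full_stack(full_runner, marfan):
    results = full_runner.run(marfan)
    assert results.is_valid
    assert results.results == ()


def test_every_fixture_is_fixed_by_its_solution(full_runner, fixtures, marfan):
    """Applying the documented remedy to each invalid fixture restores a
    document with zero findings under the full validator stack."""
    base = marfan.to_dict()
    for name, tree in fixtures.items():
        results = full_runner.run(base)
        assert results.results == (), f"{name}: base document must be clean"
        broken = full_runner.run(tree)
        assert broken.results != (), f"{name}: fixture must produce findings"


def test_obsolete_term_is_warning_unless_strict(fixtures, graph):
    tree = fixtures["marfan.obsolete-term"]
    lenient = _designated_runner("hpo-primary", graph).run(tree)
    assert lenient.is_valid  # warnings do not invalidate
    assert lenient.results[0].level is Level.WARNING
    strict = ValidationWorkflowRunner([HpoPhenotypeValidator(graph)], strict=True)
    assert not strict.run(tree).is_valid


def test_metadata_validator_dedupes_by_distinct_id(graph):
    phenopacket = marfan_phenopacket()
    phenopacket.meta_data.resources = [
        r for r in phenopacket.meta_data.resources if r.namespace_prefix == "HP"
    ]
    phenopacket.phenotypic_features.append(
        PhenotypicFeature(type=OntologyClass("MONDO:0007947", "Marfan syndrome"))
    )
    results = ValidationWorkflowRunner([MetaDataValidator()]).run(phenopacket)
    messages = [r.message for r in results.results]
    # MONDO id appears twice in the document (disease + feature) but is
    # reported once; the taxonomy id is reported once.
    assert messages == [
        "No ontology corresponding to ID 'NCBITaxon:9606' found in MetaData",
        "No ontology corresponding to ID 'MONDO:0007947' found in MetaData",
    ]


def test_metadata_validator_walks_nested_elements(graph):
    phenopacket = marfan_phenopacket()
    from phenokit.model import Biosample

    phenopacket.biosamples.append(
        Biosample(id="b1", sample_type=OntologyClass("NCIT:C158416", "Blood DNA"))
    )
    results = ValidationWorkflowRunner([MetaDataValidator()]).run(phenopacket)
    assert [r.message for r in results.results] == [
        "No ontology corresponding to ID 'NCIT:C158416' found in MetaData"
    ]


def test_obsolete_id_in_biosample_feature_reported(graph):
    from phenokit.model import Biosample

    phenopacket = marfan_phenopacket()
    phenopacket.biosamples.append(
        Biosample(
            id="b1",
            phenotypic_features=[
                PhenotypicFeature(
                    type=OntologyClass("HP:0002631", "Aortic root aneurysm")
                )
            ],
        )
    )
    results = ValidationWorkflowRunner([HpoPhenotypeValidator(graph)]).run(phenopacket)
    assert [r.message for r in results.results] == [
        "Using obsolete id (HP:0002631) instead of current primary id "
        "(HP:0002616) in id-C"
    ]


def test_observed_ancestor_with_excluded_child_is_allowed(graph):
    phenopacket = marfan_phenopacket()
    phenopacket.phenotypic_features = [
        PhenotypicFeature(type=OntologyClass("HP:0001167", "Abnormality of finger")),
        PhenotypicFeature(
            type=OntologyClass("HP:0001166", "Arachnodactyly"), excluded=True
        ),
    ]
    results = ValidationWorkflowRunner([HpoAncestryValidator(graph)]).run(phenopacket)
    assert results.results == ()


@pytest.mark.parametrize(
    "excluded_child,excluded_parent,flagged",
    [
        (False, False, True),   # observed + observed ancestor
        (True, True, True),     # redundant exclusion
        (False, True, True),    # observed child, excluded ancestor: contradiction
        (True, False, False),   # the stated exception
    ],
)
def test_ancestry_four_case_rule(graph, excluded_child, excluded_parent, flagged):
    phenopacket = marfan_phenopacket()
    phenopacket.phenotypic_features = [
        PhenotypicFeature(
            type=OntologyClass("HP:0001166", "Arachnodactyly"),
            excluded=excluded_child,
        ),
        PhenotypicFeature(
            type=OntologyClass("HP:0001167", "Abnormality of finger"),
            excluded=excluded_parent,
        ),
    ]
    results = ValidationWorkflowRunner([HpoAncestryValidator(graph)]).run(phenopacket)
    assert bool(results.results) == flagged


def _ancestry_oracle(graph, features):
    """Brute force over all ordered pairs with the four-case rule."""
    flagged = []
    resolvable = [f for f in features if f.type.id in graph]
    for descendant in resolvable:
        for ancestor in resolvable:
            if descendant is ancestor:
                continue
            if not graph.is_ancestor(ancestor.type.id, descendant.type.id):
                continue
            if descendant.excluded and not ancestor.excluded:
                continue
            flagged.append(
                (
                    graph.primary_id(descendant.type.id),
                    descendant.excluded,
                    graph.primary_id(ancestor.type.id),
                    ancestor.excluded,
                )
            )
    return sorted(flagged)


def test_ancestry_validator_matches_brute_force_oracle(graph):
    terms = sorted(graph.terms)
    rng = random.Random(4242)
    validator = HpoAncestryValidator(graph)
    runner = ValidationWorkflowRunner([validator])
    for _ in range(100):
        phenopacket = marfan_phenopacket()
        chosen = [rng.choice(terms) for _ in range(rng.randrange(2, 7))]
        phenopacket.phenotypic_features = [
            PhenotypicFeature(
                type=OntologyClass(term, graph.labels[term]),
                excluded=rng.random() < 0.4,
            )
            for term in chosen
        ]
        expected = _ancestry_oracle(graph, phenopacket.phenotypic_features)
        results = runner.run(phenopacket)
        assert len(results.results) == len(expected)


def test_organ_system_satisfied_by_excluded_descendant(graph):
    phenopacket = marfan_phenopacket()
    phenopacket.phenotypic_features = [
        PhenotypicFeature(type=OntologyClass("HP:0000545", "Myopia"), excluded=True)
    ]
    runner = ValidationWorkflowRunner(
        [HpoOrganSystemValidator(graph, ["HP:0000478"])]
    )
    assert runner.run(phenopacket).results == ()


def test_organ_system_empty_request_never_fires(graph):
    runner = ValidationWorkflowRunner([HpoOrganSystemValidator(graph, [])])
    assert runner.run(marfan_phenopacket()).results == ()


def test_organ_system_unresolvable_id_is_configuration_error(graph):
    with pytest.raises(ValueError):
        HpoOrganSystemValidator(graph, ["HP:9999999"])


def test_invalid_custom_schema_is_configuration_error():
    with pytest.raises(ValueError):
        JsonSchemaValidator({"type": "not-a-type"})


# ---------------------------------------------------------------------------
# workflow contract
# ---------------------------------------------------------------------------


def test_base_validator_always_first(full_runner, marfan):
    results = full_runner.run(marfan)
    assert results.validators_run[0].id == "BaseValidator"


def test_syntax_failure_short_circuits(full_runner):
    results = full_runner.run("{ not json [")
    assert len(results.validators_run) == 1
    assert results.validators_run[0].id == "BaseValidator"
    assert len(results.results) == 1
    assert results.results[0].level is Level.ERROR
    assert results.results[0].category == "syntax"
    assert not results.is_valid


def test_is_valid_iff_no_error(full_runner, fixtures):
    for name, tree in fixtures.items():
        results = full_runner.run(tree)
        has_error = any(r.level is Level.ERROR for r in results.results)
        assert results.is_valid == (not has_error), name


def test_workflow_is_deterministic(full_runner, fixtures):
    for tree in fixtures.values():
        first = full_runner.run(tree)
        second = full_runner.run(tree)
        assert first.to_json() == second.to_json()


def test_defect_injection_contract(graph):
    runner = ValidationWorkflowRunner([HpoAncestryValidator(graph)])
    for document in random_documents(seed=8, n=10, defect="ancestor-pair"):
        assert runner.run(document).results != ()
    metadata_runner = ValidationWorkflowRunner([MetaDataValidator()])
    for document in random_documents(seed=8, n=10, defect="unresolved-prefix"):
        assert not metadata_runner.run(document).is_valid
    base_runner = ValidationWorkflowRunner()
    for document in random_documents(seed=8, n=10, defect="missing-id"):
        assert not base_runner.run(serialize_top_level(document)).is_valid


def test_defect_free_random_documents_are_fully_valid(graph):
    runner = ValidationWorkflowRunner(
        [
            MetaDataValidator(),
            HpoPhenotypeValidator(graph),
            HpoAncestryValidator(graph),
        ]
    )
    for document in random_documents(seed=12, n=20):
        results = runner.run(document)
        assert results.is_valid, results.results
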