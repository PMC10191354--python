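"""v1-to-v2 migration: carry-over fidelity and the variant policy."""

import pytest

from phenokit import v1 as m1
from phenokit.converter import (
    ConversionOptions,
    ConversionPolicyError,
    convert_v1_to_v2,
)
from phenokit.generate import random_documents
from phenokit.model import (
    AcmgPathogenicityClassification,
    OntologyClass,
    TherapeuticActionability,
    serialize_top_level,
)
from phenokit.validation import ValidationWorkflowRunner


def _simple_v1(n_diseases=1, n_variants=0):
    return m1.V1Phenopacket(
        id="v1-doc",
        subject=m1.V1Individual(id="s1", age_at_collection=m1.V1Age(age="P30Y")),
        phenotypic_features=[
            m1.V1PhenotypicFeature(type=OntologyClass("HP:0001166", "Arachnodactyly")),
            m1.V1PhenotypicFeature(
                type=OntologyClass("HP:0000545", "Myopia"), negated=True
            ),
        ],
        variants=[
            m1.V1Variant(
                hgvs_allele=m1.HgvsAllele(id=f"v{i}", hgvs="NM_000138.5:c.8326C>T"),
                zygosity=OntologyClass("GENO:0000135", "heterozygous"),
            )
            for i in range(n_variants)
        ],
        diseases=[
            m1.V1Disease(term=OntologyClass(f"MONDO:000794{i}", f"disease {i}"))
            for i in range(n_diseases)
        ],
        meta_data=m1.V1MetaData(
            created="2019-01-01T00:00:00Z",
            created_by="tester",
            phenopacket_schema_version="1.0",
        ),
    )


def test_no_variant_conversion_carries_everything_over():
    phenopacket, report = convert_v1_to_v2(_simple_v1())
    assert phenopacket.id == "v1-doc"
    assert phenopacket.subject.time_at_last_encounter.age.iso8601duration == "P30Y"
    assert [f.type.id for f in phenopacket.phenotypic_features] == [
        "HP:0001166",
        "HP:0000545",
    ]
    assert phenopacket.phenotypic_features[1].excluded
    assert [d.term.id for d in phenopacket.diseases] == ["MONDO:0007940"]
    assert phenopacket.interpretations == []
    assert phenopacket.meta_data.phenopacket_schema_version == "2.0"
    assert report.dropped_paths == []


def test_variants_dropped_by_default_with_report_entries():
    phenopacket, report = convert_v1_to_v2(_simple_v1(n_variants=2))
    assert phenopacket.interpretations == []
    assert report.dropped_paths == ["variants[0]", "variants[1]"]


def test_variant_conversion_with_single_disease():
    phenopacket, _ = convert_v1_to_v2(
        _simple_v1(n_variants=1), ConversionOptions(convert_variants=True)
    )
    (interpretation,) = phenopacket.interpretations
    assert interpretation.diagnosis.disease.id == "MONDO:0007940"
    (genomic,) = interpretation.diagnosis.genomic_interpretations
    variant = genomic.variant_interpretation
    assert (
        variant.acmg_pathogenicity_classification
        is AcmgPathogenicityClassification.NOT_PROVIDED
    )
    assert (
        variant.therapeutic_actionability
        is TherapeuticActionability.UNKNOWN_ACTIONABILITY
    )
    assert variant.variation_descriptor.allelic_state.id == "GENO:0000135"
    assert variant.variation_descriptor.expressions[0].value == "NM_000138.5:c.8326C>T"


@pytest.mark.parametrize("n_diseases", [0, 2])
def test_variant_conversion_requires_exactly_one_disease(n_diseases):
    with pytest.raises(ConversionPolicyError):
        convert_v1_to_v2(
            _simple_v1(n_diseases=n_diseases, n_variants=1),
            ConversionOptions(convert_variants=True),
        )


def test_multiple_variants_collapse_into_one_interpretation():
    phenopacket, _ = convert_v1_to_v2(
        _simple_v1(n_variants=3), ConversionOptions(convert_variants=True)
    )
    (interpretation,) = phenopacket.interpretations
    assert len(interpretation.diagnosis.genomic_interpretations) == 3
    assert interpretation.diagnosis.disease.id == "MONDO:0007940"


def _feature_key_v1(feature):
    onset = feature.class_of_onset.id if feature.class_of_onset else None
    return (feature.type.id, feature.negated, onset)


def _feature_key_v2(feature):
    onset = None
    if feature.onset is not None and feature.onset.ontology_class is not None:
        onset = feature.onset.ontology_class.id
    return (feature.type.id, feature.excluded, onset)


def test_phenotype_multiset_preserved_on_random_documents():
    for document in random_documents(seed=17, n=50, version="v1"):
        phenopacket, _ = convert_v1_to_v2(document)
        assert sorted(map(_feature_key_v1, document.phenotypic_features)) == sorted(
            map(_feature_key_v2, phenopacket.phenotypic_features)
        )


def test_converted_random_documents_pass_base_validation():
    runner = ValidationWorkflowRunner()
    for document in random_documents(seed=23, n=50, version="v1"):
        phenopacket, _ = convert_v1_to_v2(document)
        results = runner.run(serialize_top_level(phenopacket, "json"))
        assert results.is_valid, results.results


def test_no_variant_is_dropped_silently():
    for document in random_documents(seed=31, n=30, version="v1"):
        _, report = convert_v1_to_v2(document)
        dropped_variants = [p for p in report.dropped_paths if p.startswith("variants")]
        assert len(dropped_variants) == len(document.variants)


def test_ignored_v1_paths_flow_into_report():
    ignored = []
    document = m1.parse_v1(
        '{"id": "x", "htsFiles": [{"uri": "file://x.bam"}], '
        '"diseases": [], "metaData": {"created": "2019-01-01T00:00:00Z"}}',
        ignored=ignored,
    )
    _, report = convert_v1_to_v2(document, ignored_paths=ignored)
    assert "htsFiles" in report.dropped_paths
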