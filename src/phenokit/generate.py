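"""Deterministic example documents and seeded random-document generation.

This module produces

* a worked rare-disease (Marfan-style) phenopacket for subject ``id-C``,
* the nine named invalid fixtures, each the valid example with exactly one
  defect, used to exercise every off-the-shelf validator,
* seeded random v1 and v2 phenopackets for round-trip and conversion
  properties, with optional named defect injection.

Everything is generated in memory; the CLI ``examples`` command writes the
documents to disk.  All content is fixed (a constant creation timestamp),
so regenerated output is byte-identical across runs.
"""

from __future__ import annotations

import copy
import random

from . import vocab
from .builders import (
    DiseaseBuilder,
    IndividualBuilder,
    MeasurementBuilder,
    MetaDataBuilder,
    PhenopacketBuilder,
    PhenotypicFeatureBuilder,
)
from .model import (
    Biosample,
    MedicalAction,
    MetaData,
    OntologyClass,
    Phenopacket,
    PhenotypicFeature,
    Procedure,
    Sex,
    TimeElement,
)
from . import v1 as m1

__all__ = [
    "CREATED",
    "CREATOR",
    "marfan_phenopacket",
    "valid_examples",
    "INVALID_FIXTURE_NAMES",
    "invalid_fixture_trees",
    "random_phenopacket",
    "random_v1_phenopacket",
    "random_documents",
]

CREATED = "2022-06-11T12:00:00Z"
CREATOR = "phenokit"

_HOMO_SAPIENS = OntologyClass("NCBITaxon:9606", "Homo sapiens")
_MARFAN = OntologyClass("MONDO:0007947", "Marfan syndrome")


def _standard_metadata(keys: list[str]) -> MetaData:
    builder = MetaDataBuilder(CREATED, CREATOR)
    for key in keys:
        builder.resource(vocab.resource_version(key, "2022-06-11"))
    return builder.build()


def marfan_phenopacket() -> Phenopacket:
    """The worked rare-disease example: proband ``id-C`` with HPO-coded
    eye, aortic and skeletal findings and a Marfan-syndrome diagnosis."""
    subject = (
        IndividualBuilder("id-C")
        .age_at_last_encounter("P27Y")
        .male()
        .taxonomy(_HOMO_SAPIENS)
        .build()
    )
    ectopia = (
        PhenotypicFeatureBuilder(OntologyClass("HP:0001083", "Ectopia lentis"))
        .modifier(vocab.constant("Laterality", "bilateral"))
        .childhood_onset()
        .build()
    )
    aneurysm = (
        PhenotypicFeatureBuilder(OntologyClass("HP:0002616", "Aortic root aneurysm"))
        .severe()
        .iso8601_onset("P11Y4M")
        .build()
    )
    arachnodactyly = PhenotypicFeatureBuilder(
        OntologyClass("HP:0001166", "Arachnodactyly")
    ).build()
    disease = DiseaseBuilder(_MARFAN).iso8601_onset("P10Y").build()
    return (
        PhenopacketBuilder(
            "marfan-example", _standard_metadata(["hpo", "mondo", "ncbitaxon"])
        )
        .subject(subject)
        .phenotypic_feature(ectopia)
        .phenotypic_feature(aneurysm)
        .phenotypic_feature(arachnodactyly)
        .disease(disease)
        .build()
    )


def _bp_measurement_phenopacket() -> Phenopacket:
    """Example with a quantitative measurement (systolic blood pressure)."""
    subject = (
        IndividualBuilder("id-A")
        .age_at_last_encounter("P45Y")
        .female()
        .taxonomy(_HOMO_SAPIENS)
        .build()
    )
    systolic = MeasurementBuilder.quantity(
        OntologyClass("LOINC:8480-6", "Systolic blood pressure"),
        vocab.constant("Unit", "mmHg"),
        125.0,
    ).build()
    feature = (
        PhenotypicFeatureBuilder(OntologyClass("HP:0000098", "Tall stature"))
        .adult_onset()
        .build()
    )
    return (
        PhenopacketBuilder(
            "measurement-example",
            _standard_metadata(["hpo", "loinc", "ucum", "ncbitaxon"]),
        )
        .subject(subject)
        .phenotypic_feature(feature)
        .measurement(systolic)
        .build()
    )


def _biosample_phenopacket() -> Phenopacket:
    """Example with a blood-DNA biosample typed with registry constants."""
    subject = (
        IndividualBuilder("id-B")
        .age_at_last_encounter("P33Y2M")
        .taxonomy(_HOMO_SAPIENS)
        .build()
    )
    biosample = Biosample(
        id="biosample-1",
        sampled_tissue=vocab.constant("Organ", "kidney"),
        sample_type=vocab.constant("BiospecimenType", "bloodDNA"),
        material_sample=vocab.constant("MaterialSample", "referenceSample"),
    )
    feature = (
        PhenotypicFeatureBuilder(OntologyClass("HP:0002107", "Pneumothorax"))
        .excluded()
        .build()
    )
    return (
        PhenopacketBuilder(
            "biosample-example",
            _standard_metadata(["hpo", "uberon", "ncit", "efo", "ncbitaxon"]),
        )
        .subject(subject)
        .phenotypic_feature(feature)
        .biosample(biosample)
        .build()
    )


def valid_examples() -> dict[str, Phenopacket]:
    return {
        "marfan": marfan_phenopacket(),
        "measurement": _bp_measurement_phenopacket(),
        "biosample": _biosample_phenopacket(),
    }


INVALID_FIXTURE_NAMES = (
    "missing-fields",
    "missing-resources",
    "marfan.no-subject",
    "marfan.no-phenotype",
    "marfan.not-hpo",
    "marfan.no-time-at-last-encounter",
    "marfan.obsolete-term",
    "marfan.annotation-propagation-rule",
    "marfan.missing-eye-annotation",
)


def invalid_fixture_trees() -> dict[str, dict]:
    """The nine invalid documents, each the valid Marfan example with one
    named defect applied; keyed by fixture name."""
    base = marfan_phenopacket().to_dict()
    fixtures: dict[str, dict] = {}

    tree = copy.deepcopy(base)
    del tree["id"]
    del tree["subject"]["id"]
    del tree["phenotypicFeatures"][0]["type"]["label"]
    fixtures["missing-fields"] = tree

    tree = copy.deepcopy(base)
    tree["metaData"]["resources"] = [
        r for r in tree["metaData"]["resources"] if r["namespacePrefix"] != "NCBITaxon"
    ]
    fixtures["missing-resources"] = tree

    tree = copy.deepcopy(base)
    del tree["subject"]
    fixtures["marfan.no-subject"] = tree

    tree = copy.deepcopy(base)
    del tree["phenotypicFeatures"]
    fixtures["marfan.no-phenotype"] = tree

    tree = copy.deepcopy(base)
    tree["phenotypicFeatures"][0]["type"] = {
        "id": "NCIT:C34807",
        "label": "Ectopia Lentis",
    }
    fixtures["marfan.not-hpo"] = tree

    tree = copy.deepcopy(base)
    del tree["subject"]["timeAtLastEncounter"]
    fixtures["marfan.no-time-at-last-encounter"] = tree

    tree = copy.deepcopy(base)
    tree["phenotypicFeatures"][1]["type"]["id"] = "HP:0002631"
    fixtures["marfan.obsolete-term"] = tree

    tree = copy.deepcopy(base)
    tree["phenotypicFeatures"].append(
        {"type": {"id": "HP:0004942", "label": "Aortic aneurysm"}}
    )
    fixtures["marfan.annotation-propagation-rule"] = tree

    tree = copy.deepcopy(base)
    tree["phenotypicFeatures"] = tree["phenotypicFeatures"][1:]
    fixtures["marfan.missing-eye-annotation"] = tree

    assert tuple(fixtures) == INVALID_FIXTURE_NAMES
    return fixtures


# ---------------------------------------------------------------------------
# seeded random documents
# ---------------------------------------------------------------------------


def _phenotype_pool() -> list[OntologyClass]:
    # Leaf-ish fixture terms; avoids accidental ancestor pairs in
    # defect-free documents.
    return [
        OntologyClass("HP:0001083", "Ectopia lentis"),
        OntologyClass("HP:0000545", "Myopia"),
        OntologyClass("HP:0002616", "Aortic root aneurysm"),
        OntologyClass("HP:0001634", "Mitral valve prolapse"),
        OntologyClass("HP:0001166", "Arachnodactyly"),
        OntologyClass("HP:0001382", "Joint hypermobility"),
        OntologyClass("HP:0000098", "Tall stature"),
        OntologyClass("HP:0002107", "Pneumothorax"),
    ]


_DISEASE_POOL = [
    OntologyClass("MONDO:0007947", "Marfan syndrome"),
    OntologyClass("MONDO:0008029", "Brugada syndrome"),
    OntologyClass("MONDO:0007034", "Achondroplasia"),
]

_HGVS_POOL = [
    "NM_000138.5:c.8326C>T",
    "NM_000138.5:c.4082G>A",
    "NM_001035.3:c.6502C>T",
]


def _random_onset(rng: random.Random) -> TimeElement | None:
    choice = rng.randrange(5)
    if choice == 0:
        return None
    if choice == 1:
        return vocab.age(f"P{rng.randrange(1, 60)}Y{rng.randrange(12)}M")
    if choice == 2:
        return vocab.onset_term(rng.choice(
            ["childhoodOnset", "adultOnset", "congenitalOnset"]))
    if choice == 3:
        return vocab.gestational_age(rng.randrange(20, 41), rng.randrange(7))
    return TimeElement(timestamp=f"20{rng.randrange(10, 23)}-06-11T12:00:00Z")


def _random_feature(rng: random.Random, term: OntologyClass) -> PhenotypicFeature:
    builder = PhenotypicFeatureBuilder(term)
    if rng.random() < 0.3:
        builder.excluded()
    if rng.random() < 0.4:
        builder.severity(vocab.constant(
            "Severity", rng.choice(["mild", "moderate", "severe"])))
    if rng.random() < 0.3:
        builder.modifier(vocab.constant(
            "Laterality", rng.choice(["left", "right", "unilateral", "bilateral"])))
    onset = _random_onset(rng)
    if onset is not None:
        builder.onset(onset)
    return builder.build()


def random_phenopacket(rng: random.Random, index: int = 0) -> Phenopacket:
    """One random, structurally valid, metadata-complete v2 phenopacket."""
    subject = IndividualBuilder(f"subject-{index}")
    subject.sex(rng.choice(list(Sex)))
    if rng.random() < 0.8:
        subject.age_at_last_encounter(f"P{rng.randrange(1, 80)}Y")
    if rng.random() < 0.5:
        subject.taxonomy(_HOMO_SAPIENS)
    metadata = _standard_metadata(vocab.resource_keys())
    builder = PhenopacketBuilder(f"phenopacket-{index}", metadata).subject(
        subject.build()
    )
    terms = rng.sample(_phenotype_pool(), k=rng.randrange(1, 5))
    for term in terms:
        builder.phenotypic_feature(_random_feature(rng, term))
    if rng.random() < 0.5:
        builder.disease(
            DiseaseBuilder(rng.choice(_DISEASE_POOL)).build()
        )
    if rng.random() < 0.4:
        builder.measurement(
            MeasurementBuilder.quantity(
                OntologyClass("LOINC:8480-6", "Systolic blood pressure"),
                vocab.constant("Unit", "mmHg"),
                round(rng.uniform(90, 180), 1),
            ).build()
        )
    if rng.random() < 0.3:
        builder.biosample(
            Biosample(
                id=f"biosample-{index}",
                sampled_tissue=vocab.constant("Organ", "kidney"),
                sample_type=vocab.constant("BiospecimenType", "bloodDNA"),
            )
        )
    if rng.random() < 0.3:
        builder.medical_action(
            MedicalAction(
                procedure=Procedure(
                    code=OntologyClass("NCIT:C15189", "Biopsy"),
                    body_site=vocab.constant("Organ", "kidney"),
                )
            )
        )
    return builder.build()


def _apply_defect(phenopacket: Phenopacket, defect: str) -> Phenopacket:
    if defect == "missing-id":
        phenopacket.id = ""
    elif defect == "unresolved-prefix":
        phenopacket.phenotypic_features.append(
            PhenotypicFeature(type=OntologyClass("FAKE:0000001", "Unregistered term"))
        )
    elif defect == "ancestor-pair":
        phenopacket.phenotypic_features.extend(
            [
                PhenotypicFeature(
                    type=OntologyClass("HP:0002616", "Aortic root aneurysm")
                ),
                PhenotypicFeature(type=OntologyClass("HP:0004942", "Aortic aneurysm")),
            ]
        )
    else:
        raise ValueError(f"unknown defect {defect!r}")
    return phenopacket


def random_v1_phenopacket(rng: random.Random, index: int = 0) -> m1.V1Phenopacket:
    """One random v1 phenopacket, as the v1 era produced them: features with
    ``negated``/``classOfOnset``, optional variants with zygosity, one or
    more diseases, v1 metadata."""
    features = []
    for term in rng.sample(_phenotype_pool(), k=rng.randrange(1, 5)):
        feature = m1.V1PhenotypicFeature(type=term, negated=rng.random() < 0.3)
        if rng.random() < 0.4:
            feature.class_of_onset = vocab.constant("Onset", "childhoodOnset")
        features.append(feature)

    n_diseases = rng.choice([1, 1, 1, 2])  # mostly single-diagnosis documents
    diseases = []
    for term in rng.sample(_DISEASE_POOL, k=n_diseases):
        disease = m1.V1Disease(term=term)
        if rng.random() < 0.5:
            disease.age_of_onset = m1.V1Age(age=f"P{rng.randrange(1, 40)}Y")
        diseases.append(disease)

    variants = []
    for v_index in range(rng.randrange(0, 4)):
        if rng.random() < 0.5:
            allele = m1.HgvsAllele(
                id=f"variant-{index}-{v_index}", hgvs=rng.choice(_HGVS_POOL)
            )
            variant = m1.V1Variant(hgvs_allele=allele)
        else:
            variant = m1.V1Variant(
                vcf_allele=m1.VcfAllele(
                    genome_assembly="GRCh38",
                    id=f"variant-{index}-{v_index}",
                    chr=str(rng.randrange(1, 23)),
                    pos=rng.randrange(10_000, 1_000_000),
                    ref=rng.choice("ACGT"),
                    alt=rng.choice("ACGT"),
                )
            )
        variant.zygosity = vocab.constant(
            "AllelicState", rng.choice(["heterozygous", "homozygous"])
        )
        variants.append(variant)

    genes = []
    if rng.random() < 0.3:
        genes.append(m1.V1Gene(id="HGNC:3603", symbol="FBN1"))

    subject = m1.V1Individual(
        id=f"subject-{index}",
        age_at_collection=m1.V1Age(age=f"P{rng.randrange(1, 70)}Y"),
        sex=rng.choice(list(Sex)),
        taxonomy=_HOMO_SAPIENS,
    )
    metadata = m1.V1MetaData(
        created=CREATED,
        created_by=CREATOR,
        resources=[
            vocab.resource_version(key, "2019-01-01")
            for key in ("hpo", "mondo", "geno", "ncbitaxon")
        ],
        phenopacket_schema_version="1.0",
    )
    return m1.V1Phenopacket(
        id=f"v1-phenopacket-{index}",
        subject=subject,
        phenotypic_features=features,
        genes=genes,
        variants=variants,
        diseases=diseases,
        meta_data=metadata,
    )


def random_documents(seed: int, n: int, version: str = "v2",
                     defect: str | None = None):
    """``n`` deterministic random documents for a seed; ``version`` selects
    the v1 or v2 model, ``defect`` optionally injects a named flaw into
    every document (v2 only)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    documents = []
    for index in range(n):
        if version == "v2":
            phenopacket = random_phenopacket(rng, index)
            if defect is not None:
                phenopacket = _apply_defect(phenopacket, defect)
            documents.append(phenopacket)
        elif version == "v1":
            documents.append(random_v1_phenopacket(rng, index))
        else:
            raise ValueError(f"unknown version {version!r}")
    return documents
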