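"""Migration of v1 phenopackets to the v2 data model.

Most v1 fields have a direct v2 home and are carried over field-by-field.
The exception is the v1 ``Variant`` element, whose representation changed
incompatibly: by default variants are *dropped* and every dropped path is
recorded in the conversion report.  Variant conversion can be enabled, but
only when the source document contains exactly one disease — each variant
is then assumed causative for that diagnosis and wrapped into a
``VariantInterpretation`` with "not provided" ACMG pathogenicity and
"unknown" therapeutic actionability, since v1 carries neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import v1 as m1
from .model import (
    AcmgPathogenicityClassification,
    Age,
    Diagnosis,
    Disease,
    Evidence,
    Expression,
    GenomicInterpretation,
    Individual,
    Interpretation,
    InterpretationStatus,
    MetaData,
    Phenopacket,
    PhenotypicFeature,
    ProgressStatus,
    TherapeuticActionability,
    TimeElement,
    VariantInterpretation,
    VariationDescriptor,
    VcfRecord,
)

__all__ = [
    "ConversionOptions",
    "ConversionReport",
    "ConversionPolicyError",
    "convert_v1_to_v2",
    "convert_variant",
]

V2_SCHEMA_VERSION = "2.0"


class ConversionPolicyError(ValueError):
    """Raised when variant conversion is requested but its precondition
    (exactly one disease in the source document) does not hold."""


@dataclass
class ConversionOptions:
    convert_variants: bool = False


@dataclass
class ConversionReport:
    """Account of every v1 information item that did not survive migration."""

    dropped_paths: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _convert_time(age: m1.V1Age | None) -> TimeElement | None:
    if age is None or not age.age:
        return None
    return TimeElement(age=Age(iso8601duration=age.age))


def _convert_feature(feature: m1.V1PhenotypicFeature) -> PhenotypicFeature:
    onset = None
    if feature.class_of_onset is not None:
        onset = TimeElement(ontology_class=feature.class_of_onset)
    return PhenotypicFeature(
        description=feature.description,
        type=feature.type,
        excluded=feature.negated,
        severity=feature.severity,
        modifiers=list(feature.modifiers),
        onset=onset,
        evidence=[Evidence(e.evidence_code, e.reference) for e in feature.evidence],
    )


def _convert_disease(disease: m1.V1Disease) -> Disease:
    onset = _convert_time(disease.age_of_onset)
    if onset is None and disease.class_of_onset is not None:
        onset = TimeElement(ontology_class=disease.class_of_onset)
    return Disease(
        term=disease.term,
        onset=onset,
        disease_stage=list(disease.disease_stage),
        clinical_tnm_finding=list(disease.tnm_finding),
    )


def _convert_subject(subject: m1.V1Individual | None) -> Individual | None:
    if subject is None:
        return None
    return Individual(
        id=subject.id,
        alternate_ids=list(subject.alternate_ids),
        date_of_birth=subject.date_of_birth,
        time_at_last_encounter=_convert_time(subject.age_at_collection),
        sex=subject.sex,
        karyotypic_sex=subject.karyotypic_sex,
        taxonomy=subject.taxonomy,
    )


def _convert_metadata(meta: m1.V1MetaData | None) -> MetaData:
    meta = meta or m1.V1MetaData()
    return MetaData(
        created=meta.created,
        created_by=meta.created_by,
        submitted_by=meta.submitted_by,
        resources=list(meta.resources),
        phenopacket_schema_version=V2_SCHEMA_VERSION,
        external_references=list(meta.external_references),
    )


def _variant_descriptor(variant: m1.V1Variant, index: int) -> VariationDescriptor:
    # Allele fields are copied verbatim, never re-interpreted or normalized.
    expressions: list[Expression] = []
    vcf_record = None
    descriptor_id = f"variant-{index}"
    if variant.hgvs_allele is not None:
        expressions.append(Expression(syntax="hgvs", value=variant.hgvs_allele.hgvs))
        descriptor_id = variant.hgvs_allele.id or descriptor_id
    elif variant.vcf_allele is not None:
        allele = variant.vcf_allele
        vcf_record = VcfRecord(
            genome_assembly=allele.genome_assembly,
            chrom=allele.chr,
            pos=allele.pos,
            ref=allele.ref,
            alt=allele.alt,
        )
        descriptor_id = allele.id or descriptor_id
    elif variant.spdi_allele is not None:
        allele = variant.spdi_allele
        spdi = f"{allele.seq_id}:{allele.position}:{allele.deleted_sequence}:{allele.inserted_sequence}"
        expressions.append(Expression(syntax="spdi", value=spdi))
        descriptor_id = allele.id or descriptor_id
    elif variant.iscn_allele is not None:
        expressions.append(Expression(syntax="iscn", value=variant.iscn_allele.iscn))
        descriptor_id = variant.iscn_allele.id or descriptor_id
    return VariationDescriptor(
        id=descriptor_id,
        expressions=expressions,
        vcf_record=vcf_record,
        allelic_state=variant.zygosity,
    )


def convert_variant(variant: m1.V1Variant, sole_disease: Disease,
                    index: int = 0, subject_id: str = "") -> GenomicInterpretation:
    """Convert one v1 variant assumed causative for the sole diagnosis."""
    return GenomicInterpretation(
        subject_or_biosample_id=subject_id,
        interpretation_status=InterpretationStatus.CAUSATIVE,
        variant_interpretation=VariantInterpretation(
            acmg_pathogenicity_classification=AcmgPathogenicityClassification.NOT_PROVIDED,
            therapeutic_actionability=TherapeuticActionability.UNKNOWN_ACTIONABILITY,
            variation_descriptor=_variant_descriptor(variant, index),
        ),
    )


def convert_v1_to_v2(doc: m1.V1Phenopacket,
                     opts: ConversionOptions | None = None,
                     ignored_paths: list[str] | None = None
                     ) -> tuple[Phenopacket, ConversionReport]:
    """Map a v1 phenopacket onto the v2 model.

    Returns the v2 document plus a report listing every dropped path.
    Raises :class:`ConversionPolicyError` if variant conversion is enabled
    and the document does not contain exactly one disease.
    """
    opts = opts or ConversionOptions()
    report = ConversionReport()
    if ignored_paths:
        report.dropped_paths.extend(ignored_paths)
        report.notes.append(
            "v1 fields with no v2 analogue were ignored during parsing"
        )

    diseases = [_convert_disease(d) for d in doc.diseases]
    interpretations: list[Interpretation] = []

    for i in range(len(doc.genes)):
        report.dropped_paths.append(f"genes[{i}]")
    if doc.genes:
        report.notes.append("v1 'genes' have no faithful v2 home and were dropped")

    if doc.variants:
        if not opts.convert_variants:
            for i in range(len(doc.variants)):
                report.dropped_paths.append(f"variants[{i}]")
            report.notes.append(
                "variant conversion is disabled by default; enable it only when "
                "the single disease can be assumed to be the definitive diagnosis"
            )
        else:
            if len(doc.diseases) != 1:
                raise ConversionPolicyError(
                    f"variant conversion requires exactly one disease in the v1 "
                    f"document, found {len(doc.diseases)}; use custom conversion "
                    f"logic for multi- or zero-disease documents"
                )
            subject_id = doc.subject.id if doc.subject else ""
            genomic = [
                convert_variant(v, diseases[0], i, subject_id)
                for i, v in enumerate(doc.variants)
            ]
            interpretations.append(
                Interpretation(
                    id=f"{doc.id or 'converted'}-interpretation",
                    progress_status=ProgressStatus.SOLVED,
                    diagnosis=Diagnosis(
                        disease=diseases[0].term,
                        genomic_interpretations=genomic,
                    ),
                )
            )

    phenopacket = Phenopacket(
        id=doc.id,
        subject=_convert_subject(doc.subject),
        phenotypic_features=[_convert_feature(f) for f in doc.phenotypic_features],
        interpretations=interpretations,
        diseases=diseases,
        meta_data=_convert_metadata(doc.meta_data),
    )
    return phenopacket, report
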