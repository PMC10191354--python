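"""Fluent builders for Phenopacket Schema elements.

Required fields must be supplied when the builder is created, so a bare
``build()`` already yields an element that passes base validation for its
sub-schema.  Optional fields are set through chainable methods; setters
for scalar fields overwrite, setters for list fields append.  ``build()``
is non-destructive: a builder can be reused as a template and each call
returns an independent element.
"""

from __future__ import annotations

import copy
import re

from . import vocab
from .model import (
    Biosample,
    ComplexValue,
    Disease,
    Evidence,
    Individual,
    Interpretation,
    KaryotypicSex,
    Measurement,
    MedicalAction,
    MetaData,
    OntologyClass,
    Phenopacket,
    PhenotypicFeature,
    Procedure,
    ProgressStatus,
    Quantity,
    RadiationTherapy,
    Resource,
    Sex,
    TherapeuticRegimen,
    TimeElement,
    Treatment,
    Value,
    VitalStatus,
)

__all__ = [
    "BuilderError",
    "IndividualBuilder",
    "PhenotypicFeatureBuilder",
    "MeasurementBuilder",
    "BiosampleBuilder",
    "DiseaseBuilder",
    "MedicalActionBuilder",
    "InterpretationBuilder",
    "MetaDataBuilder",
    "resource_builder",
    "PhenopacketBuilder",
]

_RFC3339_RE = re.compile(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2})$")


class BuilderError(ValueError):
    """A required field is missing or invalid at builder creation."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise BuilderError(message)


def _require_term(value, name: str) -> OntologyClass:
    _require(isinstance(value, OntologyClass), f"'{name}' must be an OntologyClass")
    _require(bool(value.id), f"'{name}' requires a non-empty ontology class id")
    return value


class _Builder:
    """Shared chassis: holds the element under construction, returns deep
    copies from build() so the builder stays reusable."""

    _element = None

    def build(self):
        return copy.deepcopy(self._element)


class IndividualBuilder(_Builder):
    def __init__(self, id: str):
        _require(bool(id), "'id' is required to build an Individual")
        self._element = Individual(id=id)

    def time_at_last_encounter(self, when: TimeElement) -> "IndividualBuilder":
        self._element.time_at_last_encounter = when
        return self

    def age_at_last_encounter(self, iso8601: str) -> "IndividualBuilder":
        return self.time_at_last_encounter(vocab.age(iso8601))

    def sex(self, sex: Sex) -> "IndividualBuilder":
        self._element.sex = sex
        return self

    def male(self) -> "IndividualBuilder":
        return self.sex(Sex.MALE)

    def female(self) -> "IndividualBuilder":
        return self.sex(Sex.FEMALE)

    def karyotypic_sex(self, karyotype: KaryotypicSex) -> "IndividualBuilder":
        self._element.karyotypic_sex = karyotype
        return self

    def gender(self, gender: OntologyClass) -> "IndividualBuilder":
        self._element.gender = _require_term(gender, "gender")
        return self

    def taxonomy(self, taxon: OntologyClass) -> "IndividualBuilder":
        self._element.taxonomy = _require_term(taxon, "taxonomy")
        return self

    def homo_sapiens(self) -> "IndividualBuilder":
        return self.taxonomy(OntologyClass("NCBITaxon:9606", "Homo sapiens"))

    def vital_status(self, status: VitalStatus) -> "IndividualBuilder":
        self._element.vital_status = status
        return self


class PhenotypicFeatureBuilder(_Builder):
    def __init__(self, type: OntologyClass):
        self._element = PhenotypicFeature(type=_require_term(type, "type"))

    def excluded(self) -> "PhenotypicFeatureBuilder":
        self._element.excluded = True
        return self

    def severity(self, severity: OntologyClass) -> "PhenotypicFeatureBuilder":
        self._element.severity = _require_term(severity, "severity")
        return self

    def borderline(self) -> "PhenotypicFeatureBuilder":
        return self.severity(vocab.constant("Severity", "borderline"))

    def mild(self) -> "PhenotypicFeatureBuilder":
        return self.severity(vocab.constant("Severity", "mild"))

    def moderate(self) -> "PhenotypicFeatureBuilder":
        return self.severity(vocab.constant("Severity", "moderate"))

    def severe(self) -> "PhenotypicFeatureBuilder":
        return self.severity(vocab.constant("Severity", "severe"))

    def profound(self) -> "PhenotypicFeatureBuilder":
        return self.severity(vocab.constant("Severity", "profound"))

    def modifier(self, modifier: OntologyClass) -> "PhenotypicFeatureBuilder":
        self._element.modifiers.append(_require_term(modifier, "modifier"))
        return self

    def onset(self, onset: TimeElement) -> "PhenotypicFeatureBuilder":
        self._element.onset = onset
        return self

    def iso8601_onset(self, duration: str) -> "PhenotypicFeatureBuilder":
        return self.onset(vocab.age(duration))

    def childhood_onset(self) -> "PhenotypicFeatureBuilder":
        return self.onset(vocab.childhood_onset())

    def adult_onset(self) -> "PhenotypicFeatureBuilder":
        return self.onset(vocab.onset_term("adultOnset"))

    def congenital_onset(self) -> "PhenotypicFeatureBuilder":
        return self.onset(vocab.onset_term("congenitalOnset"))

    def resolution(self, resolution: TimeElement) -> "PhenotypicFeatureBuilder":
        self._element.resolution = resolution
        return self

    def evidence(self, evidence: Evidence) -> "PhenotypicFeatureBuilder":
        self._element.evidence.append(evidence)
        return self


class MeasurementBuilder(_Builder):
    def __init__(self, assay: OntologyClass, value: Value | ComplexValue):
        assay = _require_term(assay, "assay")
        if isinstance(value, Value):
            self._element = Measurement(assay=assay, value=value)
        elif isinstance(value, ComplexValue):
            self._element = Measurement(assay=assay, complex_value=value)
        else:
            raise BuilderError("'value' must be a Value or ComplexValue")

    @classmethod
    def quantity(cls, assay: OntologyClass, unit: OntologyClass,
                 value: float) -> "MeasurementBuilder":
        return cls(assay, Value(quantity=Quantity(unit=unit, value=value)))

    def time_observed(self, when: TimeElement) -> "MeasurementBuilder":
        self._element.time_observed = when
        return self

    def procedure(self, procedure: Procedure) -> "MeasurementBuilder":
        self._element.procedure = procedure
        return self


class BiosampleBuilder(_Builder):
    def __init__(self, id: str):
        _require(bool(id), "'id' is required to build a Biosample")
        self._element = Biosample(id=id)

    def sampled_tissue(self, tissue: OntologyClass) -> "BiosampleBuilder":
        self._element.sampled_tissue = _require_term(tissue, "sampledTissue")
        return self

    def sample_type(self, kind: OntologyClass) -> "BiosampleBuilder":
        self._element.sample_type = _require_term(kind, "sampleType")
        return self

    def phenotypic_feature(self, feature: PhenotypicFeature) -> "BiosampleBuilder":
        self._element.phenotypic_features.append(feature)
        return self

    def measurement(self, measurement: Measurement) -> "BiosampleBuilder":
        self._element.measurements.append(measurement)
        return self

    def pathological_stage(self, stage: OntologyClass) -> "BiosampleBuilder":
        self._element.pathological_stage = _require_term(stage, "pathologicalStage")
        return self

    def pathological_tnm_finding(self, finding: OntologyClass) -> "BiosampleBuilder":
        self._element.pathological_tnm_finding.append(
            _require_term(finding, "pathologicalTnmFinding")
        )
        return self

    def material_sample(self, status: OntologyClass) -> "BiosampleBuilder":
        self._element.material_sample = _require_term(status, "materialSample")
        return self

    def procedure(self, procedure: Procedure) -> "BiosampleBuilder":
        self._element.procedure = procedure
        return self


class DiseaseBuilder(_Builder):
    def __init__(self, term: OntologyClass):
        self._element = Disease(term=_require_term(term, "term"))

    def excluded(self) -> "DiseaseBuilder":
        self._element.excluded = True
        return self

    def onset(self, onset: TimeElement) -> "DiseaseBuilder":
        self._element.onset = onset
        return self

    def iso8601_onset(self, duration: str) -> "DiseaseBuilder":
        return self.onset(vocab.age(duration))

    def disease_stage(self, stage: OntologyClass) -> "DiseaseBuilder":
        self._element.disease_stage.append(_require_term(stage, "diseaseStage"))
        return self

    def clinical_tnm_finding(self, finding: OntologyClass) -> "DiseaseBuilder":
        self._element.clinical_tnm_finding.append(
            _require_term(finding, "clinicalTnmFinding")
        )
        return self

    def primary_site(self, site: OntologyClass) -> "DiseaseBuilder":
        self._element.primary_site = _require_term(site, "primarySite")
        return self

    def laterality(self, laterality: OntologyClass) -> "DiseaseBuilder":
        self._element.laterality = _require_term(laterality, "laterality")
        return self


class MedicalActionBuilder(_Builder):
    def __init__(self, action: Procedure | Treatment | RadiationTherapy | TherapeuticRegimen):
        if isinstance(action, Procedure):
            self._element = MedicalAction(procedure=action)
        elif isinstance(action, Treatment):
            self._element = MedicalAction(treatment=action)
        elif isinstance(action, RadiationTherapy):
            self._element = MedicalAction(radiation_therapy=action)
        elif isinstance(action, TherapeuticRegimen):
            self._element = MedicalAction(therapeutic_regimen=action)
        else:
            raise BuilderError(
                "a MedicalAction requires one of Procedure, Treatment, "
                "RadiationTherapy or TherapeuticRegimen"
            )

    def treatment_target(self, target: OntologyClass) -> "MedicalActionBuilder":
        self._element.treatment_target = _require_term(target, "treatmentTarget")
        return self

    def treatment_intent(self, intent: OntologyClass) -> "MedicalActionBuilder":
        self._element.treatment_intent = _require_term(intent, "treatmentIntent")
        return self

    def response_to_treatment(self, response: OntologyClass) -> "MedicalActionBuilder":
        self._element.response_to_treatment = _require_term(response, "responseToTreatment")
        return self

    def adverse_event(self, event: OntologyClass) -> "MedicalActionBuilder":
        self._element.adverse_events.append(_require_term(event, "adverseEvent"))
        return self

    def treatment_termination_reason(self, reason: OntologyClass) -> "MedicalActionBuilder":
        self._element.treatment_termination_reason = _require_term(
            reason, "treatmentTerminationReason"
        )
        return self


class InterpretationBuilder(_Builder):
    def __init__(self, id: str, progress_status: ProgressStatus = ProgressStatus.UNKNOWN_PROGRESS):
        _require(bool(id), "'id' is required to build an Interpretation")
        self._element = Interpretation(id=id, progress_status=progress_status)

    def diagnosis(self, diagnosis) -> "InterpretationBuilder":
        self._element.diagnosis = diagnosis
        return self

    def summary(self, summary: str) -> "InterpretationBuilder":
        self._element.summary = summary
        return self


def resource_builder(id: str, name: str, url: str, version: str,
                     namespace_prefix: str, iri_prefix: str) -> Resource:
    """Resources have six required fields and no optional ones, so the
    'builder' is a checked constructor."""
    for field_name, value in [
        ("id", id), ("name", name), ("url", url), ("version", version),
        ("namespacePrefix", namespace_prefix), ("iriPrefix", iri_prefix),
    ]:
        _require(bool(value), f"'{field_name}' is required to build a Resource")
    return Resource(id=id, name=name, url=url, version=version,
                    namespace_prefix=namespace_prefix, iri_prefix=iri_prefix)


class MetaDataBuilder(_Builder):
    def __init__(self, created: str, created_by: str):
        _require(bool(created), "'created' is required to build MetaData")
        _require(
            bool(_RFC3339_RE.match(created)),
            f"'created' must be an RFC-3339 timestamp, got {created!r}",
        )
        _require(bool(created_by), "'createdBy' is required to build MetaData")
        self._element = MetaData(
            created=created, created_by=created_by,
            phenopacket_schema_version="2.0",
        )

    def submitted_by(self, submitter: str) -> "MetaDataBuilder":
        self._element.submitted_by = submitter
        return self

    def resource(self, resource: Resource) -> "MetaDataBuilder":
        taken = {r.namespace_prefix for r in self._element.resources}
        _require(
            resource.namespace_prefix not in taken,
            f"duplicate namespace prefix {resource.namespace_prefix!r} in MetaData",
        )
        self._element.resources.append(resource)
        return self

    def hpo_version(self, version: str) -> "MetaDataBuilder":
        return self.resource(vocab.resource_version("hpo", version))


class PhenopacketBuilder(_Builder):
    def __init__(self, id: str, meta_data: MetaData):
        _require(bool(id), "'id' is required to build a Phenopacket")
        _require(isinstance(meta_data, MetaData), "'metaData' is required to build a Phenopacket")
        self._element = Phenopacket(id=id, meta_data=meta_data)

    def subject(self, subject: Individual) -> "PhenopacketBuilder":
        self._element.subject = subject
        return self

    def phenotypic_feature(self, feature: PhenotypicFeature) -> "PhenopacketBuilder":
        self._element.phenotypic_features.append(feature)
        return self

    def measurement(self, measurement: Measurement) -> "PhenopacketBuilder":
        self._element.measurements.append(measurement)
        return self

    def biosample(self, biosample: Biosample) -> "PhenopacketBuilder":
        self._element.biosamples.append(biosample)
        return self

    def interpretation(self, interpretation: Interpretation) -> "PhenopacketBuilder":
        self._element.interpretations.append(interpretation)
        return self

    def disease(self, disease: Disease) -> "PhenopacketBuilder":
        self._element.diseases.append(disease)
        return self

    def medical_action(self, action: MedicalAction) -> "PhenopacketBuilder":
        self._element.medical_actions.append(action)
        return self
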