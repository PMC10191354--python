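"""In-memory data model for the GA4GH Phenopacket Schema v2.

Messages are plain dataclasses mirroring the schema's protobuf messages.
Serialization follows the protobuf JSON mapping: lowerCamelCase keys,
enum values emitted as their UPPER_SNAKE names, and fields holding their
default value (``False``, ``0``, ``""``, empty list/map, absent message,
first enum member) omitted from output.  Parsing is strict by default and
rejects unknown keys with a path-qualified error; a lenient mode records
ignored paths instead, which the v1 converter uses.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import functools
import json
import re
import typing
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "FormatDetectionError",
    "ParseError",
    "Message",
    "OntologyClass",
    "ExternalReference",
    "Evidence",
    "GestationalAge",
    "Age",
    "AgeRange",
    "TimeInterval",
    "TimeElement",
    "Sex",
    "KaryotypicSex",
    "VitalStatus",
    "Individual",
    "PhenotypicFeature",
    "ReferenceRange",
    "Quantity",
    "Value",
    "TypedQuantity",
    "ComplexValue",
    "Procedure",
    "Measurement",
    "Biosample",
    "Disease",
    "DoseInterval",
    "Treatment",
    "RadiationTherapy",
    "TherapeuticRegimen",
    "MedicalAction",
    "Expression",
    "Extension",
    "VcfRecord",
    "VariationDescriptor",
    "AcmgPathogenicityClassification",
    "TherapeuticActionability",
    "VariantInterpretation",
    "GenomicInterpretation",
    "Diagnosis",
    "Interpretation",
    "File",
    "Resource",
    "Update",
    "MetaData",
    "Phenopacket",
    "Family",
    "Cohort",
    "detect_format",
    "parse_top_level",
    "serialize_top_level",
    "to_dict",
    "from_dict",
]

# Full ISO-8601 duration grammar (no negative durations); the string is
# stored verbatim, never normalized.
ISO8601_DURATION_RE = re.compile(
    r"^P(?!$)(\d+Y)?(\d+M)?(\d+W)?(\d+D)?"
    r"(T(?=\d)(\d+H)?(\d+M)?(\d+(?:\.\d+)?S)?)?$"
)

CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")


class FormatDetectionError(ValueError):
    """Raised when the serialization format of an input cannot be determined."""


class ParseError(ValueError):
    """Raised on malformed input; carries the offending document path."""

    def __init__(self, message: str, path: str = ""):
        super().__init__(message)
        self.path = path


def _camel(name: str) -> str:
    head, *rest = name.split("_")
    return head + "".join(p[:1].upper() + p[1:] for p in rest)


@functools.lru_cache(maxsize=None)
def _field_types(cls) -> dict[str, type]:
    return typing.get_type_hints(cls)


@functools.lru_cache(maxsize=None)
def _json_field_map(cls) -> dict[str, str]:
    """JSON key -> python attribute name."""
    return {_camel(f.name): f.name for f in dataclasses.fields(cls)}


def _unwrap_optional(tp):
    if typing.get_origin(tp) is typing.Union:
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return tp


class Message:
    """Base for all schema messages; provides dialect (de)serialization."""

    ONEOFS: dict[str, tuple[str, ...]] = {}

    def __post_init__(self):
        for group, members in self.ONEOFS.items():
            populated = [m for m in members if getattr(self, m) not in (None, "")]
            if len(populated) > 1:
                raise ValueError(
                    f"{type(self).__name__}.{group}: at most one of "
                    f"{members} may be set, got {populated}"
                )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            rendered = _render(value)
            if rendered is not None:
                out[_camel(f.name)] = rendered
        return out

    # -- deserialization -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict, *, strict: bool = True,
                  ignored: Optional[list[str]] = None, _path: str = ""):
        return from_dict(cls, data, strict=strict, ignored=ignored, _path=_path)


def _render(value):
    """Protobuf-JSON rendering; None signals 'omit this field'."""
    if value is None:
        return None
    if isinstance(value, Message):
        return value.to_dict()
    if isinstance(value, enum.Enum):
        default = next(iter(type(value)))
        if value is default:
            return None
        return value.name
    if isinstance(value, bool):
        return value or None
    if isinstance(value, (int, float)):
        return value if value != 0 else None
    if isinstance(value, str):
        return value or None
    if isinstance(value, list):
        if not value:
            return None
        return [
            item.to_dict() if isinstance(item, Message)
            else item.name if isinstance(item, enum.Enum)
            else item
            for item in value
        ]
    if isinstance(value, dict):
        return dict(value) or None
    raise TypeError(f"cannot serialize {type(value).__name__}")


def _convert(tp, value, path: str, strict: bool, ignored):
    tp = _unwrap_optional(tp)
    origin = typing.get_origin(tp)
    if origin is list:
        if not isinstance(value, list):
            raise ParseError(f"expected a list at '{path}'", path)
        (elem_tp,) = typing.get_args(tp)
        return [
            _convert(elem_tp, v, f"{path}[{i}]", strict, ignored)
            for i, v in enumerate(value)
        ]
    if origin is dict:
        if not isinstance(value, dict):
            raise ParseError(f"expected a map at '{path}'", path)
        return {str(k): str(v) for k, v in value.items()}
    if isinstance(tp, type) and issubclass(tp, Message):
        if not isinstance(value, dict):
            raise ParseError(f"expected an object at '{path}'", path)
        return from_dict(tp, value, strict=strict, ignored=ignored, _path=path)
    if isinstance(tp, type) and issubclass(tp, enum.Enum):
        if isinstance(value, str):
            try:
                return tp[value]
            except KeyError:
                raise ParseError(
                    f"'{value}' is not a member of {tp.__name__} at '{path}'", path
                ) from None
        if isinstance(value, int):
            members = list(tp)
            if 0 <= value < len(members):
                return members[value]
        raise ParseError(f"bad enum value {value!r} at '{path}'", path)
    if tp is str:
        if isinstance(value, (datetime.datetime, datetime.date)):
            return _rfc3339(value)
        if not isinstance(value, str):
            raise ParseError(f"expected a string at '{path}'", path)
        return value
    if tp is bool:
        if not isinstance(value, bool):
            raise ParseError(f"expected a boolean at '{path}'", path)
        return value
    if tp is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ParseError(f"expected an integer at '{path}'", path)
        return value
    if tp is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParseError(f"expected a number at '{path}'", path)
        return float(value)
    raise TypeError(f"unsupported field type {tp!r} at '{path}'")


def _rfc3339(value) -> str:
    if isinstance(value, datetime.datetime):
        text = value.isoformat()
        if value.tzinfo is None:
            text += "Z"
        return text.replace("+00:00", "Z")
    return value.isoformat()


def from_dict(cls, data: dict, *, strict: bool = True,
              ignored: Optional[list[str]] = None, _path: str = ""):
    """Build a message from a protobuf-JSON tree.

    With ``strict=True`` unknown keys raise :class:`ParseError`; otherwise
    their paths are appended to ``ignored`` (when given) and skipped.
    """
    if not isinstance(data, dict):
        raise ParseError(f"expected an object at '{_path or '<root>'}'", _path)
    jmap = _json_field_map(cls)
    hints = _field_types(cls)
    kwargs = {}
    for key, value in data.items():
        sub_path = f"{_path}.{key}" if _path else key
        attr = jmap.get(key)
        if attr is None:
            if strict:
                raise ParseError(f"unknown field '{sub_path}'", sub_path)
            if ignored is not None:
                ignored.append(sub_path)
            continue
        kwargs[attr] = _convert(hints[attr], value, sub_path, strict, ignored)
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ParseError(f"{exc} at '{_path or '<root>'}'", _path) from exc


def to_dict(message: Message) -> dict:
    return message.to_dict()


# ---------------------------------------------------------------------------
# Messages
# ---------------------------------------------------------------------------


@dataclass
class OntologyClass(Message):
    """The schema's universal coding element: a CURIE ``id`` plus ``label``."""

    id: str = ""
    label: str = ""


@dataclass
class ExternalReference(Message):
    id: str = ""
    reference: str = ""
    description: str = ""


@dataclass
class Evidence(Message):
    evidence_code: Optional[OntologyClass] = None
    reference: Optional[ExternalReference] = None


@dataclass
class GestationalAge(Message):
    weeks: int = 0
    days: int = 0


@dataclass
class Age(Message):
    iso8601duration: str = ""


@dataclass
class AgeRange(Message):
    start: Optional[Age] = None
    end: Optional[Age] = None


@dataclass
class TimeInterval(Message):
    start: str = ""
    end: str = ""


@dataclass
class TimeElement(Message):
    """Tagged union of the ways the schema expresses a point in time.

    Exactly one of ``gestational_age``, ``age``, ``age_range``,
    ``ontology_class`` (an onset term), ``timestamp`` or ``interval``
    is populated.
    """

    ONEOFS = {
        "element": (
            "gestational_age",
            "age",
            "age_range",
            "ontology_class",
            "timestamp",
            "interval",
        )
    }

    gestational_age: Optional[GestationalAge] = None
    age: Optional[Age] = None
    age_range: Optional[AgeRange] = None
    ontology_class: Optional[OntologyClass] = None
    timestamp: str = ""
    interval: Optional[TimeInterval] = None


class Sex(enum.Enum):
    UNKNOWN_SEX = 0
    FEMALE = 1
    MALE = 2
    OTHER_SEX = 3


class KaryotypicSex(enum.Enum):
    UNKNOWN_KARYOTYPE = 0
    XX = 1
    XY = 2
    XO = 3
    XXY = 4
    XXX = 5
    XXYY = 6
    XXXY = 7
    XXXX = 8
    XYY = 9
    OTHER_KARYOTYPE = 10


class VitalStatusValue(enum.Enum):
    UNKNOWN_STATUS = 0
    ALIVE = 1
    DECEASED = 2


@dataclass
class VitalStatus(Message):
    status: VitalStatusValue = VitalStatusValue.UNKNOWN_STATUS
    time_of_death: Optional[TimeElement] = None
    cause_of_death: Optional[OntologyClass] = None
    survival_time_in_days: int = 0


@dataclass
class Individual(Message):
    """Demographics of the proband (or a family member)."""

    id: str = ""
    alternate_ids: list[str] = field(default_factory=list)
    date_of_birth: str = ""
    time_at_last_encounter: Optional[TimeElement] = None
    vital_status: Optional[VitalStatus] = None
    sex: Sex = Sex.UNKNOWN_SEX
    karyotypic_sex: KaryotypicSex = KaryotypicSex.UNKNOWN_KARYOTYPE
    gender: Optional[OntologyClass] = None
    taxonomy: Optional[OntologyClass] = None


@dataclass
class PhenotypicFeature(Message):
    """A clinical sign, symptom or finding, HPO-coded in typical use."""

    description: str = ""
    type: Optional[OntologyClass] = None
    excluded: bool = False
    severity: Optional[OntologyClass] = None
    modifiers: list[OntologyClass] = field(default_factory=list)
    onset: Optional[TimeElement] = None
    resolution: Optional[TimeElement] = None
    evidence: list[Evidence] = field(default_factory=list)


@dataclass
class ReferenceRange(Message):
    unit: Optional[OntologyClass] = None
    low: float = 0.0
    high: float = 0.0


@dataclass
class Quantity(Message):
    unit: Optional[OntologyClass] = None
    value: float = 0.0
    reference_range: Optional[ReferenceRange] = None


@dataclass
class Value(Message):
    ONEOFS = {"value": ("quantity", "ontology_class")}

    quantity: Optional[Quantity] = None
    ontology_class: Optional[OntologyClass] = None


@dataclass
class TypedQuantity(Message):
    type: Optional[OntologyClass] = None
    quantity: Optional[Quantity] = None


@dataclass
class ComplexValue(Message):
    typed_quantities: list[TypedQuantity] = field(default_factory=list)


@dataclass
class Procedure(Message):
    code: Optional[OntologyClass] = None
    body_site: Optional[OntologyClass] = None
    performed: Optional[TimeElement] = None


@dataclass
class Measurement(Message):
    ONEOFS = {"measurement_value": ("value", "complex_value")}

    description: str = ""
    assay: Optional[OntologyClass] = None
    value: Optional[Value] = None
    complex_value: Optional[ComplexValue] = None
    time_observed: Optional[TimeElement] = None
    procedure: Optional[Procedure] = None


@dataclass
class Biosample(Message):
    id: str = ""
    individual_id: str = ""
    description: str = ""
    sampled_tissue: Optional[OntologyClass] = None
    sample_type: Optional[OntologyClass] = None
    phenotypic_features: list[PhenotypicFeature] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)
    pathological_stage: Optional[OntologyClass] = None
    pathological_tnm_finding: list[OntologyClass] = field(default_factory=list)
    material_sample: Optional[OntologyClass] = None
    procedure: Optional[Procedure] = None


@dataclass
class Disease(Message):
    term: Optional[OntologyClass] = None
    excluded: bool = False
    onset: Optional[TimeElement] = None
    resolution: Optional[TimeElement] = None
    disease_stage: list[OntologyClass] = field(default_factory=list)
    clinical_tnm_finding: list[OntologyClass] = field(default_factory=list)
    primary_site: Optional[OntologyClass] = None
    laterality: Optional[OntologyClass] = None


@dataclass
class DoseInterval(Message):
    quantity: Optional[Quantity] = None
    schedule_frequency: Optional[OntologyClass] = None
    interval: Optional[TimeInterval] = None


@dataclass
class Treatment(Message):
    agent: Optional[OntologyClass] = None
    route_of_administration: Optional[OntologyClass] = None
    dose_intervals: list[DoseInterval] = field(default_factory=list)


@dataclass
class RadiationTherapy(Message):
    modality: Optional[OntologyClass] = None
    body_site: Optional[OntologyClass] = None
    dosage: int = 0
    fractions: int = 0


class RegimenStatus(enum.Enum):
    UNKNOWN_STATUS = 0
    STARTED = 1
    COMPLETED = 2
    DISCONTINUED = 3


@dataclass
class TherapeuticRegimen(Message):
    ONEOFS = {"identifier": ("external_reference", "ontology_class")}

    external_reference: Optional[ExternalReference] = None
    ontology_class: Optional[OntologyClass] = None
    start_time: Optional[TimeElement] = None
    end_time: Optional[TimeElement] = None
    regimen_status: RegimenStatus = RegimenStatus.UNKNOWN_STATUS


@dataclass
class MedicalAction(Message):
    """One of four kinds of medical action plus shared context fields."""

    ONEOFS = {
        "action": ("procedure", "treatment", "radiation_therapy", "therapeutic_regimen")
    }

    procedure: Optional[Procedure] = None
    treatment: Optional[Treatment] = None
    radiation_therapy: Optional[RadiationTherapy] = None
    therapeutic_regimen: Optional[TherapeuticRegimen] = None
    treatment_target: Optional[OntologyClass] = None
    treatment_intent: Optional[OntologyClass] = None
    response_to_treatment: Optional[OntologyClass] = None
    adverse_events: list[OntologyClass] = field(default_factory=list)
    treatment_termination_reason: Optional[OntologyClass] = None


@dataclass
class Expression(Message):
    syntax: str = ""
    value: str = ""
    version: str = ""


@dataclass
class Extension(Message):
    name: str = ""
    value: str = ""


@dataclass
class VcfRecord(Message):
    genome_assembly: str = ""
    chrom: str = ""
    pos: int = 0
    id: str = ""
    ref: str = ""
    alt: str = ""


@dataclass
class VariationDescriptor(Message):
    id: str = ""
    label: str = ""
    description: str = ""
    expressions: list[Expression] = field(default_factory=list)
    vcf_record: Optional[VcfRecord] = None
    allelic_state: Optional[OntologyClass] = None
    extensions: list[Extension] = field(default_factory=list)


class AcmgPathogenicityClassification(enum.Enum):
    NOT_PROVIDED = 0
    BENIGN = 1
    LIKELY_BENIGN = 2
    UNCERTAIN_SIGNIFICANCE = 3
    LIKELY_PATHOGENIC = 4
    PATHOGENIC = 5


class TherapeuticActionability(enum.Enum):
    UNKNOWN_ACTIONABILITY = 0
    NOT_ACTIONABLE = 1
    ACTIONABLE = 2


@dataclass
class VariantInterpretation(Message):
    acmg_pathogenicity_classification: AcmgPathogenicityClassification = (
        AcmgPathogenicityClassification.NOT_PROVIDED
    )
    therapeutic_actionability: TherapeuticActionability = (
        TherapeuticActionability.UNKNOWN_ACTIONABILITY
    )
    variation_descriptor: Optional[VariationDescriptor] = None


class InterpretationStatus(enum.Enum):
    UNKNOWN_STATUS = 0
    REJECTED = 1
    CANDIDATE = 2
    CONTRIBUTORY = 3
    CAUSATIVE = 4


@dataclass
class GenomicInterpretation(Message):
    ONEOFS = {"call": ("variant_interpretation",)}

    subject_or_biosample_id: str = ""
    interpretation_status: InterpretationStatus = InterpretationStatus.UNKNOWN_STATUS
    variant_interpretation: Optional[VariantInterpretation] = None


@dataclass
class Diagnosis(Message):
    disease: Optional[OntologyClass] = None
    genomic_interpretations: list[GenomicInterpretation] = field(default_factory=list)


class ProgressStatus(enum.Enum):
    UNKNOWN_PROGRESS = 0
    IN_PROGRESS = 1
    COMPLETED = 2
    SOLVED = 3
    UNSOLVED = 4


@dataclass
class Interpretation(Message):
    id: str = ""
    progress_status: ProgressStatus = ProgressStatus.UNKNOWN_PROGRESS
    diagnosis: Optional[Diagnosis] = None
    summary: str = ""


@dataclass
class File(Message):
    uri: str = ""
    individual_to_file_identifiers: dict[str, str] = field(default_factory=dict)
    file_attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class Resource(Message):
    """Declaration of an ontology/terminology making its CURIEs resolvable."""

    id: str = ""
    name: str = ""
    url: str = ""
    version: str = ""
    namespace_prefix: str = ""
    iri_prefix: str = ""


@dataclass
class Update(Message):
    timestamp: str = ""
    updated_by: str = ""
    comment: str = ""


@dataclass
class MetaData(Message):
    created: str = ""
    created_by: str = ""
    submitted_by: str = ""
    resources: list[Resource] = field(default_factory=list)
    updates: list[Update] = field(default_factory=list)
    phenopacket_schema_version: str = ""
    external_references: list[ExternalReference] = field(default_factory=list)


@dataclass
class Phenopacket(Message):
    """Top-level document describing one individual."""

    id: str = ""
    subject: Optional[Individual] = None
    phenotypic_features: list[PhenotypicFeature] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)
    biosamples: list[Biosample] = field(default_factory=list)
    interpretations: list[Interpretation] = field(default_factory=list)
    diseases: list[Disease] = field(default_factory=list)
    medical_actions: list[MedicalAction] = field(default_factory=list)
    files: list[File] = field(default_factory=list)
    meta_data: Optional[MetaData] = None


@dataclass
class Family(Message):
    id: str = ""
    proband: Optional[Phenopacket] = None
    relatives: list[Phenopacket] = field(default_factory=list)
    consanguinous_parents: bool = False
    files: list[File] = field(default_factory=list)
    meta_data: Optional[MetaData] = None


@dataclass
class Cohort(Message):
    id: str = ""
    description: str = ""
    members: list[Phenopacket] = field(default_factory=list)
    files: list[File] = field(default_factory=list)
    meta_data: Optional[MetaData] = None


TopLevelElement = typing.Union[Phenopacket, Family, Cohort]


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------


def detect_format(text: str) -> str:
    """Return ``"json"`` or ``"yaml"`` by inspecting the first content byte."""
    stripped = text.lstrip()
    if not stripped:
        raise FormatDetectionError("cannot detect format of empty input")
    return "json" if stripped[0] in "{[" else "yaml"


def _coerce_yaml_scalars(node):
    """YAML resolves bare timestamps to datetime; fold them back to strings."""
    if isinstance(node, dict):
        return {k: _coerce_yaml_scalars(v) for k, v in node.items()}
    if isinstance(node, list):
        return [_coerce_yaml_scalars(v) for v in node]
    if isinstance(node, (datetime.datetime, datetime.date)):
        return _rfc3339(node)
    return node


def load_tree(text: str, fmt: str = "auto") -> dict:
    """Parse JSON or YAML text into a plain tree, with positioned errors."""
    if fmt == "auto":
        fmt = detect_format(text)
    if fmt == "json":
        try:
            tree = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"JSON syntax error at line {exc.lineno}, column {exc.colno}: {exc.msg}"
            ) from exc
    elif fmt == "yaml":
        try:
            tree = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
            raise ParseError(f"YAML syntax error{where}") from exc
        tree = _coerce_yaml_scalars(tree)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not isinstance(tree, dict):
        raise ParseError("input is not a phenopacket, family, or cohort document")
    return tree


def _top_level_class(tree: dict):
    if "proband" in tree or "relatives" in tree:
        return Family
    if "members" in tree:
        return Cohort
    return Phenopacket


def parse_top_level(text: str, fmt: str = "auto", *, strict: bool = True,
                    element: Optional[str] = None,
                    ignored: Optional[list[str]] = None) -> TopLevelElement:
    """Parse JSON/YAML text into a :class:`Phenopacket`, :class:`Family`
    or :class:`Cohort`, auto-detecting both format and element kind."""
    tree = load_tree(text, fmt)
    if element:
        cls = {"phenopacket": Phenopacket, "family": Family, "cohort": Cohort}[element]
    else:
        cls = _top_level_class(tree)
    return from_dict(cls, tree, strict=strict, ignored=ignored)


def dump_json(tree: dict) -> str:
    return json.dumps(tree, indent=2, ensure_ascii=False) + "\n"


def dump_yaml(tree: dict) -> str:
    return yaml.safe_dump(tree, sort_keys=False, allow_unicode=True)


def serialize_top_level(element: Message, fmt: str = "json") -> str:
    """Serialize any message to JSON (default) or YAML in the wire dialect."""
    tree = element.to_dict()
    if fmt == "json":
        return dump_json(tree)
    if fmt == "yaml":
        return dump_yaml(tree)
    raise ValueError(f"unknown format {fmt!r}")
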