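"""Extensible validation workflow for phenopacket documents.

A workflow always starts with the mandatory *base* step — syntax plus
required-field cardinality, backed by a bundled JSON schema — followed by
any number of optional semantic validators (metadata/resource resolution,
user-supplied JSON schemas, HPO obsolete-term, annotation-propagation and
organ-system checks).  All findings are immutable :class:`ValidationResult`
values; validation never raises on bad *input*, only on bad configuration.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Optional, Union

import importlib.resources

import jsonschema

from .model import (
    Cohort,
    Family,
    Message,
    MetaData,
    OntologyClass,
    ParseError,
    Phenopacket,
    PhenotypicFeature,
    from_dict,
    load_tree,
)
from .ontology import OntologyGraph, UnknownTermError

__all__ = [
    "Level",
    "ValidatorInfo",
    "ValidationResult",
    "ValidationResults",
    "BaseValidator",
    "MetaDataValidator",
    "JsonSchemaValidator",
    "HpoPhenotypeValidator",
    "HpoAncestryValidator",
    "HpoOrganSystemValidator",
    "ValidationWorkflowRunner",
    "load_custom_schema",
    "rare_disease_validator",
    "iter_ontology_classes",
]

# Frozen message templates; the error surface is part of the contract.
REQUIRED_TEMPLATE = "'{field}' is missing but it is required"
PATTERN_TEMPLATE = "'{path}' does not match the regex pattern {pattern}"
METADATA_TEMPLATE = "No ontology corresponding to ID '{id}' found in MetaData"
OBSOLETE_TEMPLATE = (
    "Using obsolete id ({old}) instead of current primary id ({new}) in {subject}"
)
UNKNOWN_TERM_TEMPLATE = "Unknown ontology term id ({id}) in {subject}"
ANCESTRY_TEMPLATE = (
    "Phenotypic features of {subject} must not contain both an {state_term} term "
    "({term_label}, {term_id}) and an {state_ancestor} ancestor "
    "({ancestor_label}, {ancestor_id})"
)
ORGAN_SYSTEM_TEMPLATE = "Missing annotation for {label} [{id}] in {subject}"

_REQUIRED_PROP_RE = re.compile(r"^'(.*)' is a required property$")


class Level(enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class ValidatorInfo:
    id: str
    name: str
    description: str = ""


@dataclass(frozen=True)
class ValidationResult:
    validator: ValidatorInfo
    level: Level
    category: str
    message: str

    def __post_init__(self):
        if not self.message:
            raise ValueError("a validation result must carry a message")


@dataclass(frozen=True)
class ValidationResults:
    validators_run: tuple[ValidatorInfo, ...]
    results: tuple[ValidationResult, ...]

    @property
    def is_valid(self) -> bool:
        return not any(r.level is Level.ERROR for r in self.results)

    def to_dict(self) -> dict:
        return {
            "validators": [dataclasses.asdict(v) for v in self.validators_run],
            "results": [
                {
                    "validator": r.validator.id,
                    "level": r.level.value,
                    "category": r.category,
                    "message": r.message,
                }
                for r in self.results
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    def format_table(self) -> str:
        if not self.results:
            return "No validation issues found.\n"
        rows = [
            (r.validator.id, r.level.value, r.category, r.message)
            for r in self.results
        ]
        header = ("Validator", "Level", "Category", "Message")
        widths = [
            max(len(header[i]), *(len(row[i]) for row in rows)) for i in range(4)
        ]
        lines = [
            "  ".join(header[i].ljust(widths[i]) for i in range(4)),
            "  ".join("-" * widths[i] for i in range(4)),
        ]
        lines += ["  ".join(row[i].ljust(widths[i]) for i in range(4)) for row in rows]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _schema_resource(name: str) -> dict:
    text = (
        importlib.resources.files("phenokit.data.schema")
        .joinpath(name)
        .read_text("utf-8")
    )
    return json.loads(text)


def _render_path(parts) -> str:
    out = ""
    for part in parts:
        if isinstance(part, int):
            out += f"[{part}]"
        else:
            out = f"{out}.{part}" if out else part
    return out


def _doc_order(tree) -> dict[tuple, int]:
    order: dict[tuple, int] = {}
    counter = itertools.count()

    def walk(node, path):
        order[path] = next(counter)
        if isinstance(node, dict):
            for key, value in node.items():
                walk(value, path + (key,))
        elif isinstance(node, list):
            for index, value in enumerate(node):
                walk(value, path + (index,))

    walk(tree, ())
    return order


def _schema_findings(schema: dict, tree: dict, info: ValidatorInfo,
                     category: str) -> list[ValidationResult]:
    """Run a draft-07 schema and render violations with the frozen templates,
    sorted by document order."""
    validator = jsonschema.Draft7Validator(schema)
    order = _doc_order(tree)
    keyed = []
    for error in validator.iter_errors(tree):
        parent = tuple(error.absolute_path)
        if error.validator == "required":
            match = _REQUIRED_PROP_RE.match(error.message)
            prop = match.group(1) if match else "?"
            prop_schema = error.schema.get("properties", {}).get(prop, {})
            name = prop_schema.get("title") or _render_path(parent + (prop,))
            message = REQUIRED_TEMPLATE.format(field=name)
            subkey = list(error.schema.get("required", [])).index(prop) if prop in error.schema.get("required", []) else 0
        elif error.validator == "pattern":
            message = PATTERN_TEMPLATE.format(
                path=_render_path(parent), pattern=error.validator_value
            )
            subkey = 0
        else:
            message = f"'{_render_path(parent) or 'document'}': {error.message}"
            subkey = 0
        keyed.append(
            (
                order.get(parent, len(order)),
                subkey,
                ValidationResult(info, Level.ERROR, category, message),
            )
        )
    keyed.sort(key=lambda item: (item[0], item[1]))
    return [result for _, _, result in keyed]


def _contained_phenopackets(element: Message) -> list[Phenopacket]:
    if isinstance(element, Phenopacket):
        return [element]
    if isinstance(element, Family):
        return ([element.proband] if element.proband else []) + list(element.relatives)
    if isinstance(element, Cohort):
        return list(element.members)
    return []


def _subject_of(phenopacket: Phenopacket) -> str:
    if phenopacket.subject is not None and phenopacket.subject.id:
        return phenopacket.subject.id
    return phenopacket.id or "<unknown subject>"


def iter_ontology_classes(message: Message):
    """Depth-first walk yielding every OntologyClass, in field order."""
    if isinstance(message, OntologyClass):
        yield message
        return
    for f in dataclasses.fields(message):
        value = getattr(message, f.name)
        if isinstance(value, Message):
            yield from iter_ontology_classes(value)
        elif isinstance(value, list):
            for item in value:
                if isinstance(item, Message):
                    yield from iter_ontology_classes(item)


# ---------------------------------------------------------------------------
# validators
# ---------------------------------------------------------------------------


class PhenopacketValidator:
    """A single validation step; subclasses override one of the hooks."""

    info: ValidatorInfo

    def validate(self, element: Optional[Message], tree: Optional[dict]
                 ) -> list[ValidationResult]:
        raise NotImplementedError


class BaseValidator(PhenopacketValidator):
    """Mandatory first step: syntax + cardinality over the bundled schema."""

    _SCHEMAS = {
        "phenopacket": "phenopacket.schema.json",
        "family": "family.schema.json",
        "cohort": "cohort.schema.json",
    }

    def __init__(self, kind: str = "phenopacket"):
        if kind not in self._SCHEMAS:
            raise ValueError(f"no base schema for element kind {kind!r}")
        self.kind = kind
        self.schema = _schema_resource(self._SCHEMAS[kind])
        self.info = ValidatorInfo(
            id="BaseValidator",
            name="Base validator",
            description="Checks syntax and cardinality of schema components",
        )

    def validate(self, element, tree) -> list[ValidationResult]:
        if tree is None:
            return []
        return _schema_findings(self.schema, tree, self.info, "syntax")

    def syntax_error(self, message: str) -> ValidationResult:
        return ValidationResult(self.info, Level.ERROR, "syntax", message)


class MetaDataValidator(PhenopacketValidator):
    """Every CURIE prefix in the document must resolve to a MetaData
    resource; one finding per distinct unresolved id."""

    def __init__(self):
        self.info = ValidatorInfo(
            id="MetaDataValidator",
            name="MetaData validator",
            description="Checks that every ontology concept has a MetaData resource",
        )

    def validate(self, element, tree) -> list[ValidationResult]:
        if element is None:
            return []
        meta: Optional[MetaData] = getattr(element, "meta_data", None)
        prefixes = {r.namespace_prefix for r in meta.resources} if meta else set()
        findings = []
        seen: set[str] = set()
        for term in iter_ontology_classes(element):
            if not term.id or term.id in seen:
                continue
            seen.add(term.id)
            prefix = term.id.split(":", 1)[0]
            if prefix not in prefixes:
                findings.append(
                    ValidationResult(
                        self.info,
                        Level.ERROR,
                        "metadata",
                        METADATA_TEMPLATE.format(id=term.id),
                    )
                )
        return findings


class JsonSchemaValidator(PhenopacketValidator):
    """Project-specific requirements expressed as a draft-07 JSON schema."""

    def __init__(self, schema: dict, info: Optional[ValidatorInfo] = None):
        try:
            jsonschema.Draft7Validator.check_schema(schema)
        except jsonschema.SchemaError as exc:
            raise ValueError(f"invalid custom JSON schema: {exc.message}") from exc
        self.schema = schema
        self.info = info or ValidatorInfo(
            id="CustomJsonSchemaValidator",
            name=schema.get("title", "Custom JSON schema validator"),
            description=schema.get("description", ""),
        )

    def validate(self, element, tree) -> list[ValidationResult]:
        if tree is None:
            return []
        return _schema_findings(self.schema, tree, self.info, "custom-schema")


def load_custom_schema(path) -> JsonSchemaValidator:
    with open(path, encoding="utf-8") as fh:
        return JsonSchemaValidator(json.load(fh))


def rare_disease_validator() -> JsonSchemaValidator:
    """The bundled example custom schema for rare-disease diagnostics."""
    return JsonSchemaValidator(_schema_resource("rare-disease.schema.json"))


def _features_with_subject(element: Message, include_biosamples: bool
                           ) -> list[tuple[str, PhenotypicFeature]]:
    pairs = []
    for phenopacket in _contained_phenopackets(element):
        subject = _subject_of(phenopacket)
        for feature in phenopacket.phenotypic_features:
            pairs.append((subject, feature))
        if include_biosamples:
            for biosample in phenopacket.biosamples:
                for feature in biosample.phenotypic_features:
                    pairs.append((subject, feature))
    return pairs


class HpoPhenotypeValidator(PhenopacketValidator):
    """Flags phenotypic features coded with obsolete or unknown HPO ids.

    Walks top-level and biosample features.  Obsolete-id use is repairable,
    so findings are warnings by default (promote with the runner's strict
    mode)."""

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self.info = ValidatorInfo(
            id="HpoPhenotypeValidator",
            name="HPO primary-term validator",
            description="Checks that phenotype terms use current primary HPO ids",
        )

    def validate(self, element, tree) -> list[ValidationResult]:
        if element is None:
            return []
        findings = []
        for subject, feature in _features_with_subject(element, include_biosamples=True):
            term = feature.type
            if term is None or not term.id:
                continue
            if term.id not in self.graph:
                findings.append(
                    ValidationResult(
                        self.info, Level.WARNING, "unknown-term",
                        UNKNOWN_TERM_TEMPLATE.format(id=term.id, subject=subject),
                    )
                )
                continue
            primary = self.graph.primary_id(term.id)
            if primary != term.id:
                findings.append(
                    ValidationResult(
                        self.info, Level.WARNING, "obsolete-term",
                        OBSOLETE_TEMPLATE.format(
                            old=term.id, new=primary, subject=subject
                        ),
                    )
                )
        return findings


class HpoAncestryValidator(PhenopacketValidator):
    """Checks the annotation-propagation rule over the subject's features.

    A phenopacket must not assert both a term and its strict ancestor; the
    one permitted combination is an observed ancestor with an excluded
    descendant.  Ids are resolved to primary ids before comparison and each
    violating pair is reported once, ordered by the document position of the
    descendant."""

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self.info = ValidatorInfo(
            id="HpoAncestryValidator",
            name="HPO ancestry validator",
            description="Checks violations of the annotation propagation rule",
        )

    def validate(self, element, tree) -> list[ValidationResult]:
        if element is None:
            return []
        findings = []
        for phenopacket in _contained_phenopackets(element):
            subject = _subject_of(phenopacket)
            features = [
                f for f in phenopacket.phenotypic_features
                if f.type is not None and f.type.id in self.graph
            ]
            for descendant in features:
                for ancestor in features:
                    if descendant is ancestor:
                        continue
                    if not self.graph.is_ancestor(ancestor.type.id, descendant.type.id):
                        continue
                    if descendant.excluded and not ancestor.excluded:
                        continue  # observed ancestor + excluded child: allowed
                    findings.append(
                        ValidationResult(
                            self.info, Level.ERROR, "annotation-propagation",
                            ANCESTRY_TEMPLATE.format(
                                subject=subject,
                                state_term="excluded" if descendant.excluded else "observed",
                                term_label=self.graph.label(descendant.type.id),
                                term_id=self.graph.primary_id(descendant.type.id),
                                state_ancestor="excluded" if ancestor.excluded else "observed",
                                ancestor_label=self.graph.label(ancestor.type.id),
                                ancestor_id=self.graph.primary_id(ancestor.type.id),
                            ),
                        )
                    )
        return findings


class HpoOrganSystemValidator(PhenopacketValidator):
    """Requires an annotation (observed or excluded) for each selected
    organ-system term: a feature equal to, or descending from, the term."""

    def __init__(self, graph: OntologyGraph, organ_system_ids: list[str]):
        self.graph = graph
        resolved = []
        for organ_id in organ_system_ids:
            try:
                resolved.append(graph.primary_id(organ_id))
            except UnknownTermError:
                raise ValueError(
                    f"organ-system term {organ_id!r} is not in the ontology"
                ) from None
        self.organ_systems = resolved
        self.info = ValidatorInfo(
            id="HpoOrganSystemValidator",
            name="HPO organ-system validator",
            description="Checks that selected organ systems are annotated or excluded",
        )

    def validate(self, element, tree) -> list[ValidationResult]:
        if element is None:
            return []
        findings = []
        for phenopacket in _contained_phenopackets(element):
            subject = _subject_of(phenopacket)
            term_ids = {
                self.graph.primary_id(f.type.id)
                for f in phenopacket.phenotypic_features
                if f.type is not None and f.type.id in self.graph
            }
            for organ in self.organ_systems:
                satisfied = any(
                    term == organ or self.graph.is_ancestor(organ, term)
                    for term in term_ids
                )
                if not satisfied:
                    findings.append(
                        ValidationResult(
                            self.info, Level.ERROR, "organ-system",
                            ORGAN_SYSTEM_TEMPLATE.format(
                                label=self.graph.label(organ), id=organ,
                                subject=subject,
                            ),
                        )
                    )
        return findings


# ---------------------------------------------------------------------------
# workflow
# ---------------------------------------------------------------------------


class ValidationWorkflowRunner:
    """Orchestrates a validation workflow.

    The base validator always runs first and cannot be removed; extra
    validators run in registration order.  A syntax failure short-circuits
    the workflow with a single base finding.  ``strict=True`` promotes
    warnings to errors.
    """

    def __init__(self, validators: list[PhenopacketValidator] | None = None,
                 kind: str = "phenopacket", strict: bool = False):
        self.base = BaseValidator(kind)
        self.extras = list(validators or [])
        self.kind = kind
        self.strict = strict

    def add_validator(self, validator: PhenopacketValidator) -> "ValidationWorkflowRunner":
        self.extras.append(validator)
        return self

    def run(self, document: Union[str, Message, dict]) -> ValidationResults:
        tree: Optional[dict] = None
        element: Optional[Message] = None

        if isinstance(document, Message):
            element = document
            tree = document.to_dict()
        else:
            if isinstance(document, dict):
                tree = document
            else:
                try:
                    tree = load_tree(document)
                except (ParseError, ValueError) as exc:
                    return self._finish(
                        [self.base.info], [self.base.syntax_error(str(exc))]
                    )

        validators_run = [self.base.info]
        results = list(self.base.validate(element, tree))

        if element is None:
            cls = {"phenopacket": Phenopacket, "family": Family, "cohort": Cohort}[self.kind]
            try:
                element = from_dict(cls, tree, strict=False)
            except ParseError as exc:
                results.append(self.base.syntax_error(str(exc)))
                return self._finish(validators_run, results)

        for validator in self.extras:
            validators_run.append(validator.info)
            results.extend(validator.validate(element, tree))

        return self._finish(validators_run, results)

    def _finish(self, validators_run, results) -> ValidationResults:
        if self.strict:
            results = [
                ValidationResult(r.validator, Level.ERROR, r.category, r.message)
                if r.level is Level.WARNING
                else r
                for r in results
            ]
        return ValidationResults(tuple(validators_run), tuple(results))
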