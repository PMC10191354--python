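"""Predefined ontology-class constants and convenience constructors.

A curated registry of ontology terms from the recommended core
terminologies (UCUM, HPO, ECO, LOINC, NCIt, EFO, GENO, Uberon) is shipped
as a TSV data file and exposed through :func:`constant`.  The registry is
closed over the bundled resource templates: every constant's CURIE prefix
has a matching resource descriptor, so documents built purely from
registry constants can always be made metadata-complete.
"""

from __future__ import annotations

import csv
import difflib
import functools
import importlib.resources
from types import MappingProxyType

from .model import (
    Age,
    CURIE_RE,
    Expression,
    Extension,
    GestationalAge,
    ISO8601_DURATION_RE,
    OntologyClass,
    Resource,
    TimeElement,
)

__all__ = [
    "constant",
    "categories",
    "constants_in",
    "ontology_class",
    "age",
    "gestational_age",
    "childhood_onset",
    "onset_term",
    "hgvs_cdna",
    "allele_frequency",
    "resource_version",
    "resource_keys",
    "registry_rows",
]


class ConstantLookupError(KeyError):
    """Unknown (category, name) pair; the message lists near matches."""


def _data_text(filename: str) -> str:
    return (
        importlib.resources.files("phenokit.data").joinpath(filename).read_text("utf-8")
    )


@functools.lru_cache(maxsize=1)
def _registry() -> MappingProxyType:
    rows = csv.DictReader(_data_text("constants.tsv").splitlines(), delimiter="\t")
    entries = {}
    for row in rows:
        entries[(row["category"], row["name"])] = OntologyClass(
            id=row["curie"], label=row["label"]
        )
    return MappingProxyType(entries)


@functools.lru_cache(maxsize=1)
def _resource_templates() -> MappingProxyType:
    rows = csv.DictReader(_data_text("resources.tsv").splitlines(), delimiter="\t")
    return MappingProxyType({row["key"]: dict(row) for row in rows})


def registry_rows() -> list[tuple[str, str, OntologyClass]]:
    """All (category, name, term) triples, in data-file order."""
    return [(c, n, t) for (c, n), t in _registry().items()]


def categories() -> list[str]:
    seen = dict.fromkeys(c for c, _ in _registry())
    return list(seen)


def constants_in(category: str) -> dict[str, OntologyClass]:
    return {n: t for (c, n), t in _registry().items() if c == category}


def constant(category: str, name: str) -> OntologyClass:
    """Look up a predefined ontology class, e.g. ``constant("Unit", "mmHg")``.

    Returned values are shared and should be treated as immutable.
    """
    entry = _registry().get((category, name))
    if entry is None:
        candidates = [f"{c}/{n}" for c, n in _registry()]
        near = difflib.get_close_matches(f"{category}/{name}", candidates, n=3)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise ConstantLookupError(
            f"no predefined constant ({category!r}, {name!r}){hint}"
        )
    return OntologyClass(id=entry.id, label=entry.label)


def ontology_class(id: str, label: str) -> OntologyClass:
    """Construct an arbitrary ontology class from a well-formed CURIE."""
    if not CURIE_RE.match(id):
        raise ValueError(
            f"{id!r} is not a valid CURIE (expected '<prefix>:<local part>')"
        )
    return OntologyClass(id=id, label=label)


def age(iso8601: str) -> TimeElement:
    """Age as an ISO-8601 duration, e.g. ``age("P10Y4M2D")``."""
    if not ISO8601_DURATION_RE.match(iso8601):
        raise ValueError(f"{iso8601!r} is not a valid ISO-8601 duration")
    return TimeElement(age=Age(iso8601duration=iso8601))


def gestational_age(weeks: int, days: int = 0) -> TimeElement:
    if weeks < 0:
        raise ValueError(f"weeks must be non-negative, got {weeks}")
    if not 0 <= days <= 6:
        raise ValueError(f"days must be in [0, 6], got {days}")
    return TimeElement(gestational_age=GestationalAge(weeks=weeks, days=days))


def onset_term(name: str) -> TimeElement:
    """A TimeElement holding one of the registry's HPO onset terms."""
    return TimeElement(ontology_class=constant("Onset", name))


def childhood_onset() -> TimeElement:
    return onset_term("childhoodOnset")


def hgvs_cdna(expr: str) -> Expression:
    """A coding-DNA HGVS expression (VRSATILE syntax tag ``hgvs.c``)."""
    if not expr:
        raise ValueError("HGVS expression must be non-empty")
    return Expression(syntax="hgvs.c", value=expr)


def allele_frequency(frequency: float) -> Extension:
    if frequency < 0:
        raise ValueError(f"allele frequency must be non-negative, got {frequency}")
    return Extension(name="allele-frequency", value=str(float(frequency)))


def resource_keys() -> list[str]:
    return list(_resource_templates())


def resource_version(key: str, version: str) -> Resource:
    """A fully populated MetaData resource for a bundled terminology template,
    e.g. ``resource_version("hpo", "2022-06-11")``."""
    template = _resource_templates().get(key)
    if template is None:
        raise ConstantLookupError(
            f"unknown resource key {key!r}; known keys: {', '.join(resource_keys())}"
        )
    return Resource(
        id=key,
        name=template["name"],
        url=template["url"],
        version=version,
        namespace_prefix=template["namespace_prefix"],
        iri_prefix=template["iri_prefix"],
    )
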