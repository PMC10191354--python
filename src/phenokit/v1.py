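"""The subset of the Phenopacket Schema v1 data model needed for migration.

v1 documents are parsed *leniently*: fields with no v2 analogue and no role
in conversion (e.g. ``htsFiles``) are skipped and their paths recorded, so
the conversion report can account for every information item that did not
survive the migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    Evidence,
    ExternalReference,
    KaryotypicSex,
    Message,
    OntologyClass,
    ParseError,
    Resource,
    Sex,
    from_dict,
    load_tree,
)

__all__ = [
    "V1Age",
    "V1AgeRange",
    "V1Individual",
    "V1PhenotypicFeature",
    "V1Disease",
    "HgvsAllele",
    "VcfAllele",
    "SpdiAllele",
    "IscnAllele",
    "V1Variant",
    "V1Gene",
    "V1MetaData",
    "V1Phenopacket",
    "parse_v1",
]


@dataclass
class V1Age(Message):
    age: str = ""


@dataclass
class V1AgeRange(Message):
    start: Optional[V1Age] = None
    end: Optional[V1Age] = None


@dataclass
class V1Individual(Message):
    ONEOFS = {"age": ("age_at_collection", "age_range_at_collection")}

    id: str = ""
    alternate_ids: list[str] = field(default_factory=list)
    date_of_birth: str = ""
    age_at_collection: Optional[V1Age] = None
    age_range_at_collection: Optional[V1AgeRange] = None
    sex: Sex = Sex.UNKNOWN_SEX
    karyotypic_sex: KaryotypicSex = KaryotypicSex.UNKNOWN_KARYOTYPE
    taxonomy: Optional[OntologyClass] = None


@dataclass
class V1PhenotypicFeature(Message):
    """v1 feature; ``negated`` became ``excluded`` and the ontology-class
    onset moved inside v2's TimeElement, otherwise fields match v2."""

    description: str = ""
    type: Optional[OntologyClass] = None
    negated: bool = False
    severity: Optional[OntologyClass] = None
    modifiers: list[OntologyClass] = field(default_factory=list)
    class_of_onset: Optional[OntologyClass] = None
    evidence: list[Evidence] = field(default_factory=list)


@dataclass
class V1Disease(Message):
    ONEOFS = {"onset": ("age_of_onset", "class_of_onset")}

    term: Optional[OntologyClass] = None
    age_of_onset: Optional[V1Age] = None
    class_of_onset: Optional[OntologyClass] = None
    disease_stage: list[OntologyClass] = field(default_factory=list)
    tnm_finding: list[OntologyClass] = field(default_factory=list)


@dataclass
class HgvsAllele(Message):
    id: str = ""
    hgvs: str = ""


@dataclass
class VcfAllele(Message):
    vcf_version: str = ""
    genome_assembly: str = ""
    id: str = ""
    chr: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""
    info: str = ""


@dataclass
class SpdiAllele(Message):
    id: str = ""
    seq_id: str = ""
    position: int = 0
    deleted_sequence: str = ""
    inserted_sequence: str = ""


@dataclass
class IscnAllele(Message):
    id: str = ""
    iscn: str = ""


@dataclass
class V1Variant(Message):
    ONEOFS = {"allele": ("hgvs_allele", "vcf_allele", "spdi_allele", "iscn_allele")}

    hgvs_allele: Optional[HgvsAllele] = None
    vcf_allele: Optional[VcfAllele] = None
    spdi_allele: Optional[SpdiAllele] = None
    iscn_allele: Optional[IscnAllele] = None
    zygosity: Optional[OntologyClass] = None


@dataclass
class V1Gene(Message):
    id: str = ""
    symbol: str = ""


@dataclass
class V1MetaData(Message):
    created: str = ""
    created_by: str = ""
    submitted_by: str = ""
    resources: list[Resource] = field(default_factory=list)
    phenopacket_schema_version: str = ""
    external_references: list[ExternalReference] = field(default_factory=list)


@dataclass
class V1Phenopacket(Message):
    id: str = ""
    subject: Optional[V1Individual] = None
    phenotypic_features: list[V1PhenotypicFeature] = field(default_factory=list)
    genes: list[V1Gene] = field(default_factory=list)
    variants: list[V1Variant] = field(default_factory=list)
    diseases: list[V1Disease] = field(default_factory=list)
    meta_data: Optional[V1MetaData] = None


def parse_v1(text_or_tree, fmt: str = "auto",
             ignored: Optional[list[str]] = None) -> V1Phenopacket:
    """Parse a v1 phenopacket from JSON/YAML text or an already-loaded tree.

    Unknown v1 fields are ignored, with their paths appended to ``ignored``.
    """
    tree = text_or_tree
    if isinstance(tree, str):
        tree = load_tree(tree, fmt)
    if not isinstance(tree, dict):
        raise ParseError("v1 input is not a phenopacket document")
    return from_dict(V1Phenopacket, tree, strict=False, ignored=ignored)
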