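# Methods and design notes

## The data model and its wire dialect

The Phenopacket Schema is defined in protobuf; its JSON interchange form
follows the protobuf-JSON mapping. phenokit's dataclass model reproduces
that mapping so its output is byte-compatible with the wider phenopacket
ecosystem:

* field names serialize as lowerCamelCase;
* enum values serialize as their `UPPER_SNAKE` member names, and the first
  (zero) member of each enum — `UNKNOWN_SEX`, `NOT_PROVIDED`,
  `UNKNOWN_ACTIONABILITY`, … — is the default and is omitted;
* fields holding their default (`false`, `0`, `""`, empty list/map, absent
  message) are omitted, which makes *absent* and *default* equivalent.
  Equality over the model follows the same rule, so
  `parse(serialize(x)) == x` holds even when defaults were spelled out in
  the input;
* timestamps are RFC-3339 strings; ages are ISO-8601 duration strings
  nested as `{"age": {"iso8601duration": "P10Y4M2D"}}`.

Durations are validated against the full ISO-8601 duration grammar
(years, months, weeks, days, and time components) but stored verbatim —
no normalization, since `P1Y` and `P12M` are clinically distinct claims of
precision. Union-typed messages (`TimeElement`, `MedicalAction`'s action,
`Measurement`'s value, the v1 `Variant` allele) enforce at most one
populated alternative at construction.

Parsing is strict by default: unknown keys raise a path-qualified error
(`unknown field 'subject.notAField'`). A lenient mode skips unknown keys
and records their paths; the v1 parser uses it so the conversion report
can account for fields with no v2 home (e.g. `htsFiles`). YAML input is
loaded with the safe loader and bare timestamp scalars are folded back to
strings, so JSON and YAML trees are interchangeable.

## Builders

Every builder takes its element's required fields as constructor
arguments (`PhenotypicFeatureBuilder(type)`,
`PhenopacketBuilder(id, meta_data)`, `MetaDataBuilder(created, created_by)`,
`resource_builder(… all six …)`), so an untouched `build()` already
satisfies the element's sub-schema. The required-field set per element is
exactly the `required` list of the bundled base JSON schema, which is the
single source of truth. `build()` returns a deep copy, making builders
reusable templates; list setters append, scalar setters overwrite.
Builders enforce structural invariants only (one-of exclusivity, value
ranges, CURIE shape); document-wide rules belong to the validation
workflow.

## Vocabulary registry

Constants live in `data/constants.tsv` (category, name, CURIE, label,
source terminology) and are loaded once at first use. Sixteen categories
are provided: Unit, Severity, Laterality, SpatialPattern, Evidence,
Gender, BiospecimenType, PathologicalTnm, MaterialSample, AllelicState,
DiseaseStage, Organ, Response, AdministrationRoute, Onset, and
TreatmentTermination. The registry is deliberately closed over the
resource templates in `data/resources.tsv`: every CURIE prefix used by a
constant has a template, so `resource_version(key, version)` can always
complete the metadata of a registry-built document.

One curation note: GENO assigns *distinct* ids to homozygous
(GENO:0000136), heterozygous (GENO:0000135) and hemizygous (GENO:0000134).
Secondary sources sometimes collide homozygous and hemizygous onto one id;
the registry keeps the ontology's distinct ids.

## v1 → v2 conversion policy

Everything with a stable v2 home is carried field-by-field: `negated` →
`excluded`, the v1 ontology-class onset → a `TimeElement` holding that
class, `ageAtCollection` → `timeAtLastEncounter`, disease `tnmFinding` →
`clinicalTnmFinding`, metadata resources verbatim, and
`phenopacketSchemaVersion` set to `"2.0"`.

The v1 `Variant` element has no faithful v2 equivalent, so conversion is
lossy by policy:

* **default** — variants are dropped; the report lists `variants[i]` for
  each, so nothing disappears silently;
* **opt-in** (`convert_variants=True` / `--convert-variants`) — allowed
  only when the document holds exactly one disease, which is then assumed
  to be the definitive diagnosis. Each variant becomes a
  `GenomicInterpretation` (status CAUSATIVE) under a single SOLVED
  `Interpretation`; since v1 carries neither, ACMG pathogenicity is set to
  NOT_PROVIDED and therapeutic actionability to UNKNOWN_ACTIONABILITY.
  Allele fields are copied without re-interpretation (HGVS/SPDI/ISCN into
  `expressions`, VCF alleles into a `vcfRecord`); a variant with no
  zygosity simply omits `allelicState` while the two enum defaults still
  apply. Zero or multiple diseases raise a policy error directing the
  user to custom conversion logic.

v1 `genes` have no v2 home under this policy and are dropped with a
report entry.

## Validation workflow

The runner guarantees: the base validator is always first and cannot be
removed; a syntax failure yields a single base ERROR and short-circuits;
`is_valid` ⇔ no ERROR-level finding; identical input and stack give
byte-identical serialized results.

Message templates are frozen string constants — the error surface is part
of the API:

| category | template |
|---|---|
| syntax (required) | `'<path>' is missing but it is required` |
| custom-schema (pattern) | `'<path>' does not match the regex pattern <pattern>` |
| metadata | `No ontology corresponding to ID '<id>' found in MetaData` |
| obsolete-term | `Using obsolete id (<old>) instead of current primary id (<new>) in <subject>` |
| annotation-propagation | `Phenotypic features of <subject> must not contain both an <observed/excluded> term (<label>, <id>) and an <observed/excluded> ancestor (<label>, <id>)` |
| organ-system | `Missing annotation for <label> [<id>] in <subject>` |

Design choices that were genuinely open:

* **Schema draft.** Draft-07 for the base and user schemas (broadest
  validator support). Required-property violations are rendered with the
  dotted path; when the failing property's sub-schema carries a `title`,
  the title is printed instead — the bundled rare-disease schema titles
  its `subject` property "Subject", giving the human-oriented message
  `'Subject' is missing but it is required` at the document root while
  nested paths stay in lowerCamel form.
* **Finding order.** Schema findings are sorted by document position of
  the parent node (then by position in the `required` list), so messages
  appear in document order regardless of validator-internal iteration.
* **Levels.** Base, metadata, custom-schema, ancestry and organ-system
  findings are ERROR. Obsolete-id and unknown-term findings are WARNING:
  they are repairable and non-breaking. The runner's `strict` mode (CLI
  `--strict`) promotes warnings to errors.
* **Deduplication.** The metadata validator reports each distinct
  unresolved id once (first-occurrence order); the ancestry validator
  reports each violating ordered pair once, ordered by the descendant's
  document position.
* **Traversal scope.** The metadata validator walks the *entire* document
  for ontology classes (features, measurements, biosamples, medical
  actions, interpretations, …). The obsolete-term validator checks
  top-level and biosample features. The ancestry and organ-system
  validators examine the subject's top-level features only, since they
  encode claims about the proband's phenotype, not about a specimen.
* **Annotation-propagation rule.** For an ordered pair (descendant,
  ancestor) after obsolete-id resolution: observed+observed,
  excluded+excluded, and observed-descendant+excluded-ancestor are all
  violations; excluded-descendant+observed-ancestor is the permitted
  refinement ("has an eye abnormality, but not myopia"). An organ-system
  requirement is satisfied by an observed *or excluded* feature at or
  below the organ-system term.
* **Family/Cohort.** These are parse/serialize/base-validate citizens;
  semantic validators apply themselves to each contained phenopacket.
  Dedicated builders are not provided.

## Ontology service and fixture

Only `is_a` edges are honoured at load; the is-a graph must be a DAG
(checked with Kahn's algorithm), obsolete terms enter the
obsolete→primary map via their replacement (chains are collapsed so the
map is idempotent), and a replacement pointing outside the graph is a
load error. IRI-form identifiers are normalized to CURIEs by their last
path segment. `is_ancestor` is strict — a term is never its own ancestor.

The bundled fixture is a deterministic 26-term miniature of the HPO:
a root, a phenotypic-abnormality branch with eye, cardiovascular
(aorta → aortic aneurysm → aortic root aneurysm, with the obsolete
alternate id HP:0002631), skeletal (finger → arachnodactyly), growth and
respiratory sub-branches, and a clinical-modifier branch with onset and
severity terms. Every term keeps its public HPO id and label; no ids are
invented. The fixture exercises every validator code path but is four
orders of magnitude smaller than the real HPO, so tests that pass here
demonstrate the *logic*, not performance or coverage over the full
ontology; the real `hp.json` loads through the same code path.

## Random-document generation

`generate.random_documents(seed, n, version, defect)` produces
deterministic pseudo-random v1/v2 phenopackets drawing terms from the
fixture ontology and the constant registry; the phenotype pool uses
leaf-level terms so defect-free documents never violate the ancestry rule
by accident. v1 documents mirror the habits of real v1 corpora: mostly
single-diagnosis documents (75 %), 0–3 variants with GENO zygosity, v1
metadata with resource declarations. Named defects (`missing-id`,
`unresolved-prefix`, `ancestor-pair`) inject exactly one violation class
for validator testing. Generated data does not emulate free-text noise,
multi-ontology coding habits, or longitudinal records; passing tests say
nothing about those aspects of real data.

## Problem sizes and verification

The acceptance script measures: construction-route parity (3 routes),
the nine-fixture error surface, conversion policy over 100 random v1
documents, round-trip identity over 200 random v2 documents in JSON and
YAML plus cross-format, ancestry-validator agreement with an all-pairs
brute-force oracle over 200 random feature sets, `is_ancestor` agreement
with an independent transitive-closure oracle over 100 random 50-node
DAGs, and the workflow contract. These sizes keep the whole script under
ten seconds on one CPU while giving each stochastic property enough
trials to be meaningful; all quantities are recomputed at run time from
the given seed.
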