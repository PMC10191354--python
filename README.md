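# phenokit

A Python library and command-line tool for **constructing, converting, and
validating GA4GH Phenopackets** — the ISO-standardized schema for sharing
disease and phenotype information about an individual person or biosample.

phenokit is aimed at people who produce or consume phenopackets in
phenotype-driven genomic diagnostics and translational research: developers
of ETL pipelines that turn registry or EHR data into phenopackets, authors
of data-entry tools that must emit *valid* documents, and bioinformaticians
who need to check cohorts of phenopackets before analysis.

## What it does

* **Typed data model + wire dialect** (`phenokit.model`). Dataclasses for
  every Phenopacket Schema v2 message (`Phenopacket`, `Individual`,
  `PhenotypicFeature`, `Measurement`, `Biosample`, `Disease`,
  `MedicalAction`, `Interpretation`, `MetaData`, …) with JSON/YAML
  (de)serialization in the protobuf-JSON dialect: lowerCamelCase keys,
  enums as `UPPER_SNAKE` strings, default-valued fields omitted. Parsing is
  strict (unknown fields are rejected with a path-qualified error) with an
  optional lenient mode.
* **Concise builders** (`phenokit.builders`). Fluent builders that demand
  each element's required fields at creation time and chain optional
  setters, so invalid elements are hard to construct.
* **Curated vocabulary** (`phenokit.vocab`). Predefined ontology-class
  constants from the recommended core terminologies (HPO severity,
  laterality and onset terms; UCUM units; LOINC gender codes; NCIt
  biospecimen, TNM, response and administration-route concepts; GENO
  allelic states; ECO evidence codes; EFO sample status), shipped as a TSV
  registry, plus convenience constructors (`ontology_class`, `age`,
  `gestational_age`, `hgvs_cdna`, `allele_frequency`, `resource_version`).
* **v1 → v2 conversion** (`phenokit.converter`). Field-by-field migration
  of v1 phenopackets. Because the v1 `Variant` element changed
  incompatibly, variants are **dropped by default** and every dropped path
  is recorded in a conversion report; variant conversion can be enabled
  when the document has exactly one disease, in which case each variant
  becomes a `VariantInterpretation` assumed causative, with *not provided*
  ACMG pathogenicity and *unknown* therapeutic actionability.
* **Validation workflow** (`phenokit.validation`, `phenokit.ontology`). A
  mandatory base step (syntax + required-field cardinality via a bundled
  JSON schema) followed by optional semantic validators: metadata/resource
  resolution for every CURIE in the document, user-supplied JSON schemas,
  and HPO-aware checks for obsolete term ids, annotation-propagation-rule
  violations (a term and its ancestor must not both be asserted, except an
  observed ancestor with an excluded child), and required organ-system
  annotations. A miniature HPO-like ontology fixture makes all of this
  testable offline; the real HPO OBO-graph JSON file drops in unchanged.

## Worked example

```python
from phenokit import vocab
from phenokit.builders import PhenotypicFeatureBuilder
from phenokit.model import serialize_top_level

feature = (
    PhenotypicFeatureBuilder(vocab.ontology_class("HP:0001324", "Muscle weakness"))
    .severe()
    .modifier(vocab.constant("Laterality", "left"))
    .iso8601_onset("P11Y4M")
    .build()
)
print(serialize_top_level(feature, "json"))
```

prints exactly

```json
{
  "type": {
    "id": "HP:0001324",
    "label": "Muscle weakness"
  },
  "severity": {
    "id": "HP:0012828",
    "label": "Severe"
  },
  "modifiers": [
    {
      "id": "HP:0012835",
      "label": "Left"
    }
  ],
  "onset": {
    "age": {
      "iso8601duration": "P11Y4M"
    }
  }
}
```

— severe weakness of the left triceps-area musculature with onset at
eleven years four months, HPO-coded throughout, with every default field
omitted from the wire form.

Validating a broken document:

```bash
$ phenokit examples -o ex
$ phenokit validate ex/invalid/missing-fields.json
Validator      Level  Category  Message
-------------  -----  --------  ----------------------------------------------------------------
BaseValidator  ERROR  syntax    'id' is missing but it is required
BaseValidator  ERROR  syntax    'subject.id' is missing but it is required
BaseValidator  ERROR  syntax    'phenotypicFeatures[0].type.label' is missing but it is required
$ echo $?
1
```

The CLI follows UNIX conventions: data on stdin/stdout, diagnostics on
stderr, exit code 0 for valid/success, 1 for invalid documents or a
conversion-policy violation, 2 for usage/configuration errors. `convert`
auto-detects JSON vs YAML input, and the subcommands compose:

```bash
phenokit convert v1-phenopacket.yaml | phenokit validate --hpo ex/hp.fixture.json -
```

## Scope notes

Protobuf binary wire format is intentionally out of scope (JSON/YAML
only), as are native-VRS transformations and v2→v1 down-conversion. See
`docs/methods.md` for the design and modelling choices.
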