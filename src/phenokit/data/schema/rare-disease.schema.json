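{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "phenokit/custom/rare-disease",
  "title": "Rare-disease diagnostics phenopacket requirements",
  "description": "Project-specific constraints for phenotype-driven rare-disease diagnostics: the proband and their age at last encounter must be present, and phenotypic features must be HPO-coded.",
  "type": "object",
  "required": ["subject", "phenotypicFeatures"],
  "properties": {
    "subject": {
      "title": "Subject",
      "type": "object",
      "required": ["timeAtLastEncounter"]
    },
    "phenotypicFeatures": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "properties": {
          "type": {
            "type": "object",
            "properties": {
              "id": {"type": "string", "pattern": "^HP:\\d{7}$"}
            }
          }
        }
      }
    }
  }
}
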