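{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "phenokit/base/phenopacket",
  "title": "Phenopacket base requirements",
  "type": "object",
  "required": ["id", "metaData"],
  "properties": {
    "id": {"type": "string", "minLength": 1},
    "subject": {
      "type": "object",
      "required": ["id"],
      "properties": {
        "id": {"type": "string", "minLength": 1}
      }
    },
    "phenotypicFeatures": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["type"],
        "properties": {
          "type": {
            "type": "object",
            "required": ["id", "label"],
            "properties": {
              "id": {"type": "string", "minLength": 1},
              "label": {"type": "string", "minLength": 1}
            }
          }
        }
      }
    },
    "metaData": {
      "type": "object",
      "required": ["created", "createdBy", "resources"],
      "properties": {
        "created": {"type": "string", "minLength": 1},
        "createdBy": {"type": "string", "minLength": 1},
        "resources": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["id", "name", "url", "version", "namespacePrefix", "iriPrefix"]
          }
        }
      }
    }
  }
}
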