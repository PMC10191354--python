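{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "phenokit/base/family",
  "title": "Family base requirements",
  "type": "object",
  "required": ["id", "proband", "metaData"],
  "properties": {
    "id": {"type": "string", "minLength": 1},
    "metaData": {
      "type": "object",
      "required": ["created", "createdBy", "resources"]
    }
  }
}
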