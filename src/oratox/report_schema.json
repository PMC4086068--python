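{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Oral toxicity prediction report",
  "type": "object",
  "required": [
    "query_id",
    "query_smiles",
    "covered",
    "predicted_ld50_mg_kg",
    "similarity_class",
    "fragment_class",
    "consensus_class",
    "neighbors",
    "matched_fragments"
  ],
  "properties": {
    "query_id": {"type": "string"},
    "query_smiles": {"type": "string"},
    "covered": {"type": "boolean"},
    "predicted_ld50_mg_kg": {"type": ["number", "null"]},
    "similarity_class": {"type": ["integer", "null"], "minimum": 1, "maximum": 6},
    "fragment_class": {"type": ["integer", "null"], "minimum": 1, "maximum": 6},
    "consensus_class": {"type": ["integer", "null"], "minimum": 1, "maximum": 6},
    "accuracy_note": {"type": ["number", "null"]},
    "neighbors": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "smiles", "similarity", "ld50_mg_kg", "tox_class"],
        "properties": {
          "id": {"type": "string"},
          "smiles": {"type": "string"},
          "similarity": {"type": "number", "minimum": 0, "maximum": 1},
          "ld50_mg_kg": {"type": "number"},
          "tox_class": {"type": "integer", "minimum": 1, "maximum": 6}
        }
      }
    },
    "matched_fragments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["pattern", "implicated_classes"],
        "properties": {
          "pattern": {"type": "string"},
          "implicated_classes": {"type": "array", "items": {"type": "integer"}}
        }
      }
    }
  }
}
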