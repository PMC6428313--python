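{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "DBU instance document",
  "description": "A Dynamic Belief Update model-checking instance: declared symbol sets, a pointed epistemic model, a sequence of pointed event models, and a goal formula. Formula strings use the package's text syntax (~ & | -> B[agent] D[agent] T F). Relations are fully explicit; identifiers must not contain '|'.",
  "type": "object",
  "required": ["agents", "props", "state", "formula"],
  "properties": {
    "version": {"const": "1"},
    "agents": {"type": "array", "items": {"$ref": "#/$defs/id"}, "minItems": 1, "uniqueItems": true},
    "props": {"type": "array", "items": {"$ref": "#/$defs/id"}, "uniqueItems": true},
    "state": {
      "type": "object",
      "required": ["worlds", "relations", "valuation", "designated"],
      "properties": {
        "worlds": {"type": "array", "items": {"$ref": "#/$defs/id"}, "minItems": 1, "uniqueItems": true},
        "relations": {"$ref": "#/$defs/relations"},
        "valuation": {
          "type": "object",
          "additionalProperties": {"type": "array", "items": {"$ref": "#/$defs/id"}}
        },
        "designated": {"type": "array", "items": {"$ref": "#/$defs/id"}, "minItems": 1}
      }
    },
    "actions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["events", "relations", "pre", "designated"],
        "properties": {
          "events": {"type": "array", "items": {"$ref": "#/$defs/id"}, "minItems": 1, "uniqueItems": true},
          "relations": {"$ref": "#/$defs/relations"},
          "pre": {"type": "object", "additionalProperties": {"type": "string"}},
          "post": {
            "type": "object",
            "additionalProperties": {
              "type": "array",
              "items": {"type": "string", "pattern": "^~?[^|]+$"}
            }
          },
          "designated": {"type": "array", "items": {"$ref": "#/$defs/id"}, "minItems": 1}
        }
      }
    },
    "formula": {"type": "string"}
  },
  "$defs": {
    "id": {"type": "string", "minLength": 1, "pattern": "^[^|]+$"},
    "relations": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "array",
          "items": {"$ref": "#/$defs/id"},
          "minItems": 2,
          "maxItems": 2
        }
      }
    }
  }
}
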