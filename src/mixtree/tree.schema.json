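{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/mixtree/tree.schema.json",
  "title": "mixtree tree document",
  "description": "Interchange format for mixed classification trees. Routing convention: instances satisfying a node's test always go to the 'left' child. The 'repr' field duplicates the test in the canonical text grammar ('a >= 3.5', 'a == red', 'a < b', 'a < 1.25 * b').",
  "type": "object",
  "required": ["format", "format_version", "class_levels", "attributes", "config", "root"],
  "properties": {
    "format": {"const": "mixtree-tree"},
    "format_version": {"const": "1.0"},
    "routing": {"type": "string"},
    "class_levels": {
      "type": "array",
      "items": {"type": "string"},
      "minItems": 1
    },
    "attributes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "kind", "ignored"],
        "properties": {
          "name": {"type": "string"},
          "kind": {"enum": ["continuous", "nominal"]},
          "ignored": {"type": "boolean"},
          "categories": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "config": {
      "type": "object",
      "properties": {
        "families": {
          "type": "array",
          "items": {"enum": ["c45", "tsp", "wtsp"]},
          "minItems": 1
        },
        "min_node_size": {"type": "integer", "minimum": 1},
        "max_depth": {"type": "integer", "minimum": 1},
        "max_nodes": {"type": "integer", "minimum": 1},
        "entropy_threshold": {"type": "number", "minimum": 0},
        "suggestion_k": {"type": "integer", "minimum": 1},
        "max_pairs": {"type": ["integer", "null"], "minimum": 2}
      }
    },
    "root": {"$ref": "#/definitions/node"}
  },
  "definitions": {
    "node": {
      "oneOf": [
        {"$ref": "#/definitions/leaf"},
        {"$ref": "#/definitions/internal"}
      ]
    },
    "counts": {
      "type": "array",
      "items": {"type": "integer", "minimum": 0},
      "description": "One count per class level, same order as class_levels; children's counts must sum to the parent's."
    },
    "leaf": {
      "type": "object",
      "required": ["kind", "predicted_class", "train_counts"],
      "properties": {
        "kind": {"const": "leaf"},
        "id": {"type": "string"},
        "predicted_class": {"type": "string"},
        "train_counts": {"$ref": "#/definitions/counts"}
      },
      "not": {"anyOf": [
        {"required": ["test"]},
        {"required": ["left"]},
        {"required": ["right"]}
      ]}
    },
    "internal": {
      "type": "object",
      "required": ["kind", "test", "train_counts", "left", "right"],
      "properties": {
        "kind": {"const": "internal"},
        "id": {"type": "string"},
        "test": {"$ref": "#/definitions/test"},
        "train_counts": {"$ref": "#/definitions/counts"},
        "left": {"$ref": "#/definitions/node"},
        "right": {"$ref": "#/definitions/node"}
      }
    },
    "test": {
      "oneOf": [
        {
          "type": "object",
          "required": ["family", "mode", "attribute", "threshold"],
          "properties": {
            "family": {"const": "c45"},
            "mode": {"const": "threshold"},
            "attribute": {"type": "string"},
            "threshold": {"type": "number"},
            "repr": {"type": "string"}
          }
        },
        {
          "type": "object",
          "required": ["family", "mode", "attribute", "category"],
          "properties": {
            "family": {"const": "c45"},
            "mode": {"const": "category"},
            "attribute": {"type": "string"},
            "category": {"type": "string"},
            "repr": {"type": "string"}
          }
        },
        {
          "type": "object",
          "required": ["family", "attribute1", "attribute2"],
          "not": {"required": ["weight"]},
          "properties": {
            "family": {"const": "tsp"},
            "attribute1": {"type": "string"},
            "attribute2": {"type": "string"},
            "repr": {"type": "string"}
          }
        },
        {
          "type": "object",
          "required": ["family", "attribute1", "attribute2", "weight"],
          "properties": {
            "family": {"const": "wtsp"},
            "attribute1": {"type": "string"},
            "attribute2": {"type": "string"},
            "weight": {"type": "number", "exclusiveMinimum": 0},
            "repr": {"type": "string"}
          }
        }
      ]
    }
  }
}
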