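{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Computational-graph model document",
  "description": "One top-level map with exactly one model entry, keyed by model id. Collections (graphs, nodes, ports, edges) are maps keyed by id; order is recovered from key order. The same tree is carried identically by the JSON, YAML and binary (MessagePack) encodings; in JSON, non-finite floats appear as the strings 'NaN', 'Infinity' and '-Infinity'.",
  "type": "object",
  "minProperties": 1,
  "maxProperties": 1,
  "patternProperties": {
    "^[A-Za-z_][A-Za-z0-9_]*$": {"$ref": "#/$defs/model_body"}
  },
  "additionalProperties": false,
  "$defs": {
    "identifier": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9_]*$"},
    "value": {
      "description": "A scalar, a dense numeric array as nested lists, an expression string, or a non-finite marker string.",
      "anyOf": [
        {"type": "number"},
        {"type": "string"},
        {"type": "array"}
      ]
    },
    "metadata": {"type": "object"},
    "model_body": {
      "type": "object",
      "required": ["format"],
      "properties": {
        "format": {"type": "string"},
        "graphs": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/graph"}
        },
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "graph": {
      "type": "object",
      "properties": {
        "id": {"$ref": "#/$defs/identifier"},
        "nodes": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/node"}
        },
        "edges": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/edge"}
        },
        "conditions": {"$ref": "#/$defs/condition_set"},
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "node": {
      "type": "object",
      "properties": {
        "input_ports": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/input_port"}
        },
        "parameters": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/parameter"}
        },
        "functions": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/function_call"}
        },
        "output_ports": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/output_port"}
        },
        "subgraph": {"$ref": "#/$defs/graph"},
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "input_port": {
      "type": "object",
      "properties": {
        "shape": {"type": "array", "items": {"type": "integer", "minimum": 1}},
        "reduce": {"type": "string", "enum": ["error", "sum"]},
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "output_port": {
      "type": "object",
      "properties": {
        "value": {"type": "string"},
        "default_initial_value": {"$ref": "#/$defs/value"},
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "parameter": {
      "type": "object",
      "properties": {
        "value": {"$ref": "#/$defs/value"},
        "default_initial_value": {"$ref": "#/$defs/value"},
        "time_derivative": {"type": "string"},
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "function_call": {
      "type": "object",
      "required": ["function"],
      "properties": {
        "function": {"$ref": "#/$defs/identifier"},
        "args": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/value"}
        },
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "edge": {
      "type": "object",
      "required": ["sender", "sender_port", "receiver", "receiver_port"],
      "properties": {
        "sender": {"type": "string"},
        "sender_port": {"$ref": "#/$defs/identifier"},
        "receiver": {"type": "string"},
        "receiver_port": {"$ref": "#/$defs/identifier"},
        "weight": {"type": "number"},
        "metadata": {"$ref": "#/$defs/metadata"}
      }
    },
    "condition": {
      "type": "object",
      "required": ["type"],
      "properties": {
        "type": {
          "type": "string",
          "enum": ["always", "never", "every_n_calls", "after_n_calls",
                   "before_n_calls", "threshold", "time_interval",
                   "and", "or", "not", "all_have_run"]
        },
        "args": {"type": "object"}
      }
    },
    "condition_set": {
      "type": "object",
      "properties": {
        "node_specific": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/condition"}
        },
        "termination": {"$ref": "#/$defs/condition"}
      }
    }
  }
}
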