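{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Flat tensor-graph dialect",
  "description": "Single-assignment tensor graph: named inputs, an ordered op list drawn from the core operator set, named outputs. Each value name is produced exactly once and referenced only after production.",
  "type": "object",
  "required": ["inputs", "ops", "outputs"],
  "properties": {
    "inputs": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "shape": {"type": "array", "items": {"type": "integer", "minimum": 1}},
          "value": {
            "anyOf": [{"type": "number"}, {"type": "array"}]
          }
        }
      }
    },
    "ops": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["op", "inputs", "output"],
        "properties": {
          "op": {
            "type": "string",
            "enum": ["add", "sub", "mul", "div", "pow", "neg", "abs", "exp",
                     "log", "sqrt", "sin", "cos", "tanh", "sigmoid", "relu",
                     "softmax", "matmul", "transpose", "reduce_sum",
                     "reduce_mean", "reduce_max", "clip", "concat", "reshape"]
          },
          "inputs": {"type": "array", "items": {"type": "string"}},
          "output": {"type": "string"},
          "attributes": {"type": "object"}
        }
      }
    },
    "outputs": {"type": "array", "items": {"type": "string"}}
  }
}
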