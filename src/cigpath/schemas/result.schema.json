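{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://cigpath/schemas/result.schema.json",
  "title": "Contextualized guideline",
  "description": "Ordered task list with temporal roles, plus the tasks pruned under the context and the edges removed to break cycles before topological sorting.",
  "type": "object",
  "properties": {
    "entries": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {
          "taskId": {"type": "string"},
          "label": {"type": "string"},
          "role": {"enum": ["past", "present", "future"]}
        },
        "required": ["taskId", "label", "role"],
        "additionalProperties": false
      }
    },
    "pruned": {"type": "array", "items": {"type": "string"}},
    "removedEdges": {"type": "array", "items": {"type": "string"}},
    "diagnostics": {
      "type": "array",
      "items": {
        "type": "object",
        "properties": {
          "severity": {"enum": ["error", "warning"]},
          "code": {"type": "string"},
          "message": {"type": "string"},
          "elementId": {"type": ["string", "null"]}
        },
        "required": ["severity", "code", "message"],
        "additionalProperties": false
      }
    }
  },
  "required": ["entries", "pruned", "removedEdges"],
  "additionalProperties": false
}
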