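{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://cigpath/schemas/context.schema.json",
  "title": "Treatment context",
  "description": "Patient-specific facts applied to a guideline model: executed tasks with their recorded scalar outcomes, plus named variables. Executed outcomes are also visible as variables named by the task id unless shadowed by an explicit variable. Absent names evaluate to UNKNOWN.",
  "type": "object",
  "properties": {
    "executed": {
      "type": "object",
      "additionalProperties": {"type": ["boolean", "number", "string"]}
    },
    "variables": {
      "type": "object",
      "additionalProperties": {"type": ["boolean", "number", "string"]}
    }
  },
  "additionalProperties": false
}
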