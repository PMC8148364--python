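{
 "$comment": "Reference description of the hemobond module exchange document. Validation is performed structurally by hemobond.validate_io (the jsonschema package is not a dependency); this file documents the format.",
 "type": "object",
 "required": ["name", "components", "junctions", "bonds", "ports", "annotations"],
 "properties": {
  "name": {"type": "string"},
  "components": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "kind", "param"],
    "properties": {
     "id": {"type": "string"},
     "kind": {"enum": ["R", "C", "I", "Se", "Sf"]},
     "param": {"type": ["number", "string"],
               "$comment": "number, or for Sf a time-function name / external:<variable>"},
     "units": {"type": "string"},
     "state_id": {"type": "string", "$comment": "present iff kind is C or I"}
    }
   }
  },
  "junctions": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "kind"],
    "properties": {"id": {"type": "string"}, "kind": {"enum": ["zero", "one"]}}
   }
  },
  "bonds": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "tail", "head"],
    "properties": {"id": {"type": "string"}, "tail": {"type": "string"},
                   "head": {"type": "string"}},
    "$comment": "positive power flows tail -> head"
   }
  },
  "ports": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "junction", "kind"],
    "properties": {
     "id": {"type": "string"},
     "junction": {"type": "string"},
     "kind": {"enum": ["flow", "potential"]},
     "binding": {"type": ["string", "null"],
                 "$comment": "null (value 0) or a namespaced variable"}
    }
   }
  },
  "annotations": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["variable", "property_term", "entity_term"],
    "properties": {
     "variable": {"type": "string"},
     "property_term": {"type": "string",
                       "$comment": "potential | flow | time | parameter:<name>"},
     "entity_term": {"type": "string"}
    }
   }
  }
 }
}
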