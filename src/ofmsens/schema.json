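{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ofmsens native enzyme-constrained model",
 "description": "Native JSON schema for enzyme-constrained metabolic models. Scalar-or-parameter entries are either a number, the strings 'inf'/'-inf', or an object {\"param\": \"<name>\"} resolved through the parameter registry (top-level 'parameters' supplies defaults). Units: fluxes mmol/gDCW/h, kcats 1/h, molar masses mg/mmol, capacities mg/gDCW.",
 "type": "object",
 "required": ["metabolites", "reactions"],
 "$defs": {
  "value": {
   "oneOf": [
    {"type": "number"},
    {"enum": ["inf", "-inf"]},
    {"type": "object", "required": ["param"], "properties": {"param": {"type": "string"}}, "additionalProperties": false}
   ]
  }
 },
 "properties": {
  "metabolites": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id"],
    "properties": {"id": {"type": "string"}, "compartment": {"type": ["string", "null"]}}
   }
  },
  "reactions": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "stoichiometry"],
    "properties": {
     "id": {"type": "string"},
     "stoichiometry": {"type": "object", "additionalProperties": {"type": "number"}},
     "lower_bound": {"$ref": "#/$defs/value"},
     "upper_bound": {"$ref": "#/$defs/value"},
     "isozymes": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["subunit_counts"],
       "properties": {
        "subunit_counts": {"type": "object", "additionalProperties": {"type": "integer", "minimum": 1}, "minProperties": 1},
        "kcat_forward": {"$ref": "#/$defs/value"},
        "kcat_reverse": {"oneOf": [{"$ref": "#/$defs/value"}, {"type": "null"}]}
       }
      }
     },
     "objective_coefficient": {"type": "number"}
    }
   }
  },
  "genes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "molar_mass"],
    "properties": {"id": {"type": "string"}, "molar_mass": {"type": "number", "exclusiveMinimum": 0}}
   }
  },
  "pools": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "members", "capacity"],
    "properties": {
     "id": {"type": "string"},
     "members": {"type": "array", "items": {"type": "string"}, "minItems": 1},
     "capacity": {"$ref": "#/$defs/value"}
    }
   }
  },
  "fixed_fluxes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["reaction_id", "value"],
    "properties": {"reaction_id": {"type": "string"}, "value": {"$ref": "#/$defs/value"}}
   }
  },
  "objective": {"type": ["string", "null"]},
  "parameters": {"type": "object", "additionalProperties": {"type": "number"}},
  "provenance": {
   "type": "object",
   "additionalProperties": {"type": "array", "prefixItems": [{"type": "string"}, {"enum": ["fwd", "bwd"]}]}
  }
 }
}
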