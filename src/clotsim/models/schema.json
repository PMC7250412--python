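{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "clotsim reaction-network model file",
 "description": "Versioned schema for the JSON model documents consumed by clotsim.network.load_network. Concentrations are stored in the per-species display unit and converted to molar on load; rate constants are in seconds and molar.",
 "type": "object",
 "required": ["species", "reactions"],
 "properties": {
  "schema_version": {"const": 1},
  "metadata": {
   "type": "object",
   "properties": {
    "name": {"type": "string"},
    "version": {"type": "string"},
    "provenance": {"type": "string"}
   }
  },
  "species": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "initial_concentration", "unit"],
    "properties": {
     "name": {"type": "string"},
     "initial_concentration": {"type": "number", "minimum": 0},
     "unit": {"enum": ["pM", "nM", "uM", "μM", "mM", "M"]},
     "tags": {"type": "array", "items": {"type": "string"}}
    }
   }
  },
  "reactions": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "reactants", "products", "law"],
    "properties": {
     "id": {"type": "string"},
     "reactants": {"$ref": "#/$defs/side"},
     "products": {"$ref": "#/$defs/side"},
     "enzyme": {"type": "string", "description": "required for michaelis_menten law kinds; the enzyme is not consumed"},
     "modifier": {"type": "string", "description": "required for michaelis_menten_modulated; saturating cofactor species"},
     "note": {"type": "string", "description": "free-text provenance for the rate constants"},
     "law": {
      "type": "object",
      "required": ["kind", "params"],
      "oneOf": [
       {"properties": {"kind": {"const": "mass_action_irreversible"}, "params": {"type": "object", "required": ["k"]}}},
       {"properties": {"kind": {"const": "mass_action_reversible"}, "params": {"type": "object", "required": ["kon", "koff"]}}},
       {"properties": {"kind": {"const": "michaelis_menten"}, "params": {"type": "object", "required": ["kcat", "Km"]}}},
       {"properties": {"kind": {"const": "michaelis_menten_modulated"}, "params": {"type": "object", "required": ["kcat", "Km", "fold", "K_half"]}}}
      ]
     }
    }
   }
  }
 },
 "$defs": {
  "side": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["species", "stoich"],
    "properties": {
     "species": {"type": "string"},
     "stoich": {"type": "integer", "minimum": 1}
    }
   }
  }
 }
}
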