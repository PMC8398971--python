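{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "frdex parametrization interchange format",
  "description": "Per-supramolecular-complex (SC) data sufficient for fragment diabatization: reference-state labels, the reference/adiabatic overlap matrix S, adiabatic energies and transition dipoles. Produced either by an electronic-structure upstream or by the synthetic generator.",
  "type": "object",
  "required": ["format", "scs"],
  "properties": {
    "format": {"const": "frdex-parametrization-1"},
    "scs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sc_id", "labels", "n_adiabatic", "S", "energies_eV",
                     "elec_tdip_au", "mag_tdip_au"],
        "properties": {
          "sc_id": {"type": "string"},
          "labels": {
            "type": "array",
            "description": "Reference diabatic states, one per row of S.",
            "items": {
              "oneOf": [
                {
                  "type": "object",
                  "required": ["kind", "site", "state"],
                  "properties": {
                    "kind": {"const": "LE"},
                    "site": {"type": "integer"},
                    "state": {"type": "string", "examples": ["La", "Lb"]}
                  }
                },
                {
                  "type": "object",
                  "required": ["kind", "donor", "acceptor", "orbital_pair"],
                  "properties": {
                    "kind": {"const": "CT"},
                    "donor": {"type": "integer"},
                    "acceptor": {"type": "integer"},
                    "orbital_pair": {"type": "integer"}
                  }
                }
              ]
            }
          },
          "n_adiabatic": {"type": "integer", "minimum": 1},
          "S": {
            "type": "array",
            "description": "Row-major overlap matrix, n_reference x n_adiabatic.",
            "items": {"type": "array", "items": {"type": "number"}}
          },
          "energies_eV": {
            "type": "array",
            "description": "Adiabatic energies, ascending, eV.",
            "items": {"type": "number"}
          },
          "elec_tdip_au": {
            "type": "array",
            "description": "Per-adiabatic-state electric transition dipoles, a.u.",
            "items": {"type": "array", "minItems": 3, "maxItems": 3}
          },
          "elec_gauge": {"enum": ["velocity", "length"], "default": "velocity"},
          "mag_tdip_au": {
            "type": "array",
            "description": "Per-adiabatic-state magnetic transition dipoles (imaginary part as real vectors), a.u.",
            "items": {"type": "array", "minItems": 3, "maxItems": 3}
          }
        }
      }
    }
  }
}
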