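{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "homofill fill metadata",
  "type": "object",
  "required": ["model_id", "timestamp", "config", "transplants"],
  "properties": {
    "model_id": {"type": "string"},
    "timestamp": {"type": "string"},
    "config": {"type": "object"},
    "transplants": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "compound", "original_compound", "donor_entry", "donor_chain",
          "donor_copy", "evalue", "identity_fraction", "alignment_length",
          "global_rmsd", "local_rmsd", "tcs", "confidence_local",
          "confidence_tcs", "placed_chain", "mono_atomic"
        ],
        "properties": {
          "compound": {"type": "string"},
          "original_compound": {"type": "string"},
          "donor_entry": {"type": "string"},
          "donor_chain": {"type": "string"},
          "donor_copy": {"type": "integer", "minimum": 1},
          "evalue": {"type": "number", "minimum": 0},
          "identity_fraction": {"type": "number", "minimum": 0, "maximum": 1},
          "alignment_length": {"type": "integer", "minimum": 1},
          "global_rmsd": {"type": "number", "minimum": 0},
          "local_rmsd": {"type": "number", "minimum": 0},
          "tcs": {"type": "number", "minimum": 0},
          "confidence_local": {"enum": ["high", "medium", "low"]},
          "confidence_tcs": {"enum": ["high", "medium", "low"]},
          "placed_chain": {"type": "string"},
          "mono_atomic": {"type": "boolean"}
        }
      }
    }
  }
}
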