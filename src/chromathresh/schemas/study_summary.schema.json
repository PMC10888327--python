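{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Study summary",
  "type": "object",
  "required": [
    "n_subjects",
    "n_retested",
    "classification_kappa",
    "icc_per_axis",
    "icc_mean",
    "bland_altman",
    "retest_mean_abs_diff",
    "kappa_table"
  ],
  "properties": {
    "n_subjects": {"type": "integer", "minimum": 0},
    "n_retested": {"type": "integer", "minimum": 0},
    "classification_kappa": {"type": "number", "minimum": -1, "maximum": 1},
    "icc_per_axis": {
      "type": "object",
      "required": ["protan", "deutan", "tritan"],
      "additionalProperties": {"type": "number"}
    },
    "icc_mean": {"type": "number"},
    "bland_altman": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["mean_difference", "sd_difference", "loa_lower", "loa_upper"],
        "additionalProperties": {"type": "number"}
      }
    },
    "retest_mean_abs_diff": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {"type": "number"}
      }
    },
    "kappa_table": {
      "type": "object",
      "required": ["categories", "counts"],
      "properties": {
        "categories": {"type": "array", "items": {"type": "string"}},
        "counts": {"type": "array", "items": {"type": "array", "items": {"type": "integer"}}}
      }
    }
  }
}
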