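{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Plate ground-truth sidecar",
  "type": "object",
  "required": [
    "axis",
    "requested_de",
    "achieved_de",
    "arrow_rgb",
    "background_rgb",
    "arrow_direction_deg",
    "arrowhead_center_deg",
    "arrowhead_center_px",
    "arrow_polygon_deg",
    "hit_radius_cm",
    "is_catch_trial",
    "n_circles"
  ],
  "properties": {
    "axis": {"type": "string", "enum": ["protan", "deutan", "tritan"]},
    "requested_de": {"type": "number", "minimum": 0},
    "achieved_de": {"type": "number", "minimum": 0},
    "arrow_rgb": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}, "minItems": 3, "maxItems": 3},
    "background_rgb": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}, "minItems": 3, "maxItems": 3},
    "arrow_direction_deg": {"type": "number"},
    "arrowhead_center_deg": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
    "arrowhead_center_px": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
    "arrow_polygon_deg": {"type": "array", "items": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}},
    "hit_radius_cm": {"type": "number", "exclusiveMinimum": 0},
    "is_catch_trial": {"type": "boolean"},
    "seed": {"type": ["integer", "null"]},
    "n_circles": {"type": "integer", "minimum": 0}
  }
}
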