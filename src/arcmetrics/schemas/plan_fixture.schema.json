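{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "arcmetrics plan fixture",
  "description": "Plain-JSON dialect for VMAT plans, semantically equivalent to a DICOM RT Plan as far as the metrics in this package are concerned.",
  "type": "object",
  "required": ["patient_id", "group", "prescription_gy", "fractions", "arcs"],
  "properties": {
    "patient_id": {"type": "string"},
    "group": {"type": ["string", "null"], "description": "study group label, e.g. A/B/C"},
    "prescription_gy": {"type": "number", "exclusiveMinimum": 0},
    "fractions": {"type": "integer", "minimum": 1},
    "leaf_width_mm": {"type": "number", "exclusiveMinimum": 0, "default": 5.0},
    "arcs": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["increment_deg", "direction", "arc_mu", "control_points"],
        "properties": {
          "increment_deg": {"type": "number", "enum": [15, 30]},
          "direction": {"type": "string", "enum": ["CW", "CCW"]},
          "arc_mu": {"type": "number", "exclusiveMinimum": 0},
          "control_points": {
            "type": "array",
            "minItems": 2,
            "items": {
              "type": "object",
              "required": ["gantry_deg", "cum_weight", "left_mm", "right_mm"],
              "properties": {
                "gantry_deg": {"type": "number", "minimum": 0, "exclusiveMaximum": 360},
                "cum_weight": {"type": "number", "minimum": 0, "maximum": 1},
                "collimator_deg": {"type": "number", "default": 0},
                "left_mm": {"type": "array", "items": {"type": "number"}},
                "right_mm": {"type": "array", "items": {"type": "number"}}
              }
            }
          }
        }
      }
    }
  }
}
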