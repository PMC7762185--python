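{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Beam column condition configuration",
  "description": "Maps each 96-well plate column to the ion species, delivered dose ladder and beam-quality metrics (LET_d, y_d) at that column's depth along the beam path.",
  "type": "object",
  "required": ["conditions"],
  "properties": {
    "conditions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["column", "ion", "doses"],
        "properties": {
          "column": {"type": "integer", "minimum": 1, "maximum": 12},
          "ion": {"enum": ["photon", "proton", "helium", "carbon"]},
          "doses": {
            "type": "array",
            "items": {"type": "number", "minimum": 0},
            "minItems": 1,
            "description": "Gy per delivered exposure level, strictly increasing"
          },
          "let_d": {"type": "number", "exclusiveMinimum": 0, "description": "dose-averaged LET, keV/um"},
          "y_d": {"type": "number", "exclusiveMinimum": 0, "description": "dose-mean lineal energy, keV/um"},
          "depth_label": {"type": "string"}
        }
      }
    }
  }
}
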