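{
  "$defs": {
    "WindowFractionsModel": {
      "properties": {
        "lower": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Lower",
          "type": "number"
        },
        "equal": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Equal",
          "type": "number"
        },
        "greater": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Greater",
          "type": "number"
        },
        "half_width": {
          "exclusiveMinimum": 0.0,
          "title": "Half Width",
          "type": "number"
        }
      },
      "required": [
        "lower",
        "equal",
        "greater",
        "half_width"
      ],
      "title": "WindowFractionsModel",
      "type": "object"
    }
  },
  "description": "Schema of report.json (shipped as data/report.schema.json).",
  "properties": {
    "subject_id": {
      "title": "Subject Id",
      "type": "string"
    },
    "genetic_risk": {
      "exclusiveMinimum": 0.0,
      "title": "Genetic Risk",
      "type": "number"
    },
    "overall_risk": {
      "exclusiveMinimum": 0.0,
      "title": "Overall Risk",
      "type": "number"
    },
    "zone": {
      "pattern": "^(low|intermediate|high)$",
      "title": "Zone",
      "type": "string"
    },
    "percentile_population": {
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Percentile Population",
      "type": "number"
    },
    "percentile_cases": {
      "maximum": 1.0,
      "minimum": 0.0,
      "title": "Percentile Cases",
      "type": "number"
    },
    "window_fractions_population": {
      "$ref": "#/$defs/WindowFractionsModel"
    },
    "window_fractions_cases": {
      "$ref": "#/$defs/WindowFractionsModel"
    },
    "panel_provenance": {
      "title": "Panel Provenance",
      "type": "string"
    },
    "inputs_echo": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Inputs Echo",
      "type": "object"
    }
  },
  "required": [
    "subject_id",
    "genetic_risk",
    "overall_risk",
    "zone",
    "percentile_population",
    "percentile_cases",
    "window_fractions_population",
    "window_fractions_cases",
    "panel_provenance",
    "inputs_echo"
  ],
  "title": "RiskReportModel",
  "type": "object"
}
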