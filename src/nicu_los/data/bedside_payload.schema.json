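{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "BedsidePayload",
  "type": "object",
  "required": [
    "patient_id",
    "gestation_category",
    "predicted_los_days",
    "median_los",
    "iqr_los",
    "risk_factors",
    "guideline_version",
    "model_id",
    "generated_at"
  ],
  "properties": {
    "patient_id": {"type": "string", "minLength": 1},
    "gestation_category": {"type": "string"},
    "predicted_los_days": {"type": "integer", "minimum": 1},
    "median_los": {"type": "number"},
    "iqr_los": {"type": "number"},
    "guideline_version": {"type": "string"},
    "model_id": {"type": "string"},
    "generated_at": {"type": "string"},
    "risk_factors": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "level", "effect_days", "category", "applicable", "highlighted"],
        "properties": {
          "name": {"type": "string"},
          "level": {"type": "string"},
          "effect_days": {"type": "integer"},
          "category": {"type": "string"},
          "applicable": {"type": "boolean"},
          "highlighted": {"type": "boolean"}
        }
      }
    }
  }
}
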