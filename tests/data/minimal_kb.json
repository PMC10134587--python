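{
  "meta": {"schema_version": 1, "provenance": {"engine": "hand-written test fixture"}},
  "assessment_items": [
    {"item_id": "AI-001", "aspect": "physical", "label": "sleep pattern"},
    {"item_id": "AI-002", "aspect": "psychological", "label": "mood state"}
  ],
  "diagnoses": [
    {
      "dx_code": "DX-001",
      "label": "minimal actual diagnosis",
      "dx_type": "actual",
      "elements": [
        {"element_id": "DX-001-DC-01", "element_type": "defining_characteristic", "label": "sign one"},
        {"element_id": "DX-001-DC-02", "element_type": "defining_characteristic", "label": "sign two"},
        {"element_id": "DX-001-DC-03", "element_type": "defining_characteristic", "label": "sign three"}
      ]
    }
  ],
  "indicators": {
    "engine": "cdv",
    "params": {},
    "entries": [
      {"item_id": "AI-001", "dx_code": "DX-001", "element_id": "DX-001-DC-01", "score": 0.85, "level": "major", "engine": "cdv"}
    ]
  }
}
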