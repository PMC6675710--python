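{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "RoMMa cohort CSV row",
  "description": "One row per tumor (case). Missing values are empty fields. Encoding UTF-8; header names fixed; booleans written as true/false.",
  "type": "object",
  "required": ["case_id", "patient_id", "nottingham_score", "er_h_score", "pr_h_score"],
  "properties": {
    "case_id": {"type": "string", "description": "Opaque unique case identifier."},
    "patient_id": {"type": "string", "description": "Opaque patient identifier; several cases may share one patient."},
    "nottingham_score": {"type": "integer", "minimum": 3, "maximum": 9, "description": "Nottingham histologic grade score (tubules + pleomorphism + mitoses)."},
    "er_h_score": {"type": "integer", "minimum": 0, "maximum": 300, "description": "Modified ER H-score."},
    "pr_h_score": {"type": "integer", "minimum": 0, "maximum": 300, "description": "Modified PR H-score."},
    "her2_ihc": {"type": ["integer", "null"], "enum": [0, 1, 2, 3, null], "description": "HER-2 IHC score; 2 (equivocal) requires a FISH result to resolve."},
    "her2_fish": {"type": ["string", "null"], "enum": ["amplified", "not_amplified", null], "description": "Reflex FISH result; overrides IHC whenever present."},
    "ki67_pct": {"type": ["number", "null"], "minimum": 0, "maximum": 100, "description": "Percent Ki-67-positive tumor cells."},
    "tumor_size_cm": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "odx_rs": {"type": ["integer", "null"], "minimum": 0, "maximum": 100, "description": "Oncotype DX recurrence score, when the case was sent out."},
    "age_years": {"type": ["integer", "null"], "minimum": 0},
    "ln_status": {"type": "string", "enum": ["negative", "positive", "unknown"], "default": "unknown"},
    "lvi_status": {"type": "string", "enum": ["identified", "not_identified", "suspicious", "unknown"], "default": "unknown"},
    "recurred": {"type": ["boolean", "null"]},
    "followup_years": {"type": ["number", "null"], "minimum": 0},
    "hormonal_therapy": {"type": ["boolean", "null"]},
    "chemotherapy": {"type": ["boolean", "null"]},
    "radiation": {"type": ["boolean", "null"]}
  }
}
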