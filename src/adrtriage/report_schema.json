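{
  "format": "adrtriage-report-table",
  "version": 1,
  "dialect": {"encoding": "UTF-8", "separator": ",", "header": true},
  "ordinal_coding": {
    "1": "unassessable/unclassifiable",
    "2": "conditional/unclassified",
    "3": "possible",
    "4": "probable/likely",
    "5": "certain",
    "-1": "missing / not assessed"
  },
  "columns": [
    {"name": "casualty_assessment_1", "type": "boolean", "description": "Plausible time relationship to drug intake"},
    {"name": "casualty_assessment_2", "type": "boolean", "description": "Matched with known ADR types"},
    {"name": "casualty_assessment_3", "type": "boolean", "description": "Response to withdrawal plausible"},
    {"name": "casualty_assessment_4", "type": "boolean", "description": "Rechallenge satisfactory"},
    {"name": "casualty_assessment_5", "type": "boolean", "description": "Can be explained by other factors"},
    {"name": "severity_assessment_1", "type": "boolean", "description": "Death"},
    {"name": "severity_assessment_2", "type": "boolean", "description": "Carcinogenic, teratogenic, or birth defect"},
    {"name": "severity_assessment_3", "type": "boolean", "description": "Significant or permanent disability or damage to organ function"},
    {"name": "severity_assessment_4", "type": "boolean", "description": "Life threatening"},
    {"name": "severity_assessment_5", "type": "boolean", "description": "Admission or prolonged hospitalization"},
    {"name": "severity_assessment_6", "type": "boolean", "description": "Other significant medical events"},
    {"name": "new_ade", "type": "boolean", "description": "New (previously unknown) ADE"},
    {"name": "serious_ade", "type": "boolean", "description": "Serious ADE (OR of severity items)"},
    {"name": "gender", "type": "boolean", "description": "Patient gender flag"},
    {"name": "suspect", "type": "boolean", "description": "Suspected drug (1) vs co-occurring drug (0)"},
    {"name": "r_assess", "type": "ordinal", "description": "Causality assessment by the reporter"},
    {"name": "ri_assess", "type": "ordinal", "description": "Causality assessment by the reporter's institute"},
    {"name": "muni_assess", "type": "ordinal", "description": "Causality assessment by the municipal-level regulator"},
    {"name": "prov_assess", "type": "ordinal", "description": "Causality assessment by provincial-level experts"},
    {"name": "label", "type": "ordinal", "optional": true, "description": "Expert ground-truth label for model training (1..5, never -1)"}
  ],
  "extra_columns": "preserved verbatim as text (e.g. symptoms, drug_name, batch_number)",
  "extended_columns": [
    {"name": "auto_assess", "type": "ordinal", "description": "Model-predicted causality category"},
    {"name": "risk_s", "type": "integer", "description": "Warning-signal component lambda_s"},
    {"name": "risk_t", "type": "integer", "description": "Warning-signal component lambda_t"},
    {"name": "signal_variant", "type": "text", "description": "Formula variant used for risk_s"}
  ]
}
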