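{
 "required": {
  "V_kidney_mm3": "number",
  "compartments": "object",
  "Cth_mm": "number",
  "site_distances_mm": "array",
  "A_kidney_mm2": "number",
  "index_sqrtA_over_Cth": "number",
  "cortex_stats": "object",
  "cube_stats": "object_or_null",
  "mixture": "object",
  "thresholds_gv": "array",
  "provenance": "object"
 },
 "compartments_required": [
  "V_kidney_mm3", "V_pelvis_mm3", "V_medulla_mm3", "V_cortex_mm3",
  "pelvis_percent", "medulla_percent", "cortex_percent"
 ]
}
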