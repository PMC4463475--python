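{
  "version": 1,
  "description": "Printed outcome counts of the UKCTOCS multimodal-arm annual incidence screening (flow diagram and outcome tables of the trial report).",
  "episodes": 296911,
  "volunteers": 46237,
  "surgeries": 640,
  "screen_detected": {
    "iEOC": 133,
    "borderline": 17,
    "nonepithelial": 4,
    "PPC": 12,
    "note": "screen-positive surgeries with ovarian/tubal malignancy (154) plus primary peritoneal cancers; pathology table"
  },
  "interval": {
    "iEOC": 22,
    "borderline": 9,
    "nonepithelial": 1,
    "PPC": 3,
    "note": "cancers diagnosed clinically within 12 months of the last screening test; pathology table"
  },
  "repeat_recommendations": {
    "roca": 29584,
    "cutoff35": 5597,
    "cutoff30": 9699,
    "cutoff22": 28757,
    "note": "annual screens that led (ROCA) or would have led (fixed cutoffs) to a repeat recommendation, of 296,911"
  },
  "flagged_cases": {
    "roca": 135,
    "cutoff35": 64,
    "cutoff30": 75,
    "cutoff22": 103,
    "note": "of the 155 iEOCs within one year, those flagged at the relevant annual screen by ROCA or by a fixed cutoff"
  },
  "benign_surgeries": 441,
  "surgical_complications": 20,
  "early_stage_iEOC": 55,
  "type2_iEOC": 109,
  "clinical_evaluations": 3329,
  "incomplete_episodes": 1085,
  "printed": {
    "mms_sensitivity_pct": 85.8,
    "roca_alone_sensitivity_pct": 87.1,
    "cutoff35_sensitivity_pct": 41.3,
    "cutoff30_sensitivity_pct": 48.4,
    "cutoff22_sensitivity_pct": 66.5,
    "ppv_with_ppc_pct": 22.7,
    "ppv_ieoc_pct": 20.8,
    "surgeries_per_ieoc": 4.8,
    "specificity_pct": 99.8,
    "roca_repeat_rate_pct": 10.0,
    "cutoff35_repeat_rate_pct": 1.9,
    "cutoff30_repeat_rate_pct": 3.3,
    "cutoff22_repeat_rate_pct": 9.7,
    "early_stage_pct": 41.4,
    "type2_pct": 82.0,
    "complication_rate_pct": 4.5,
    "complication_ci_pct": [2.8, 6.9]
  }
}
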