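{
  "description": "Counts transcribed from the published results of a large clinical cytology sequencing cohort (2014-2022, targeted tumor:normal panel). Counts drive the printed-aggregate reproduction; metadata values depend on protected per-sample data and are never asserted.",
  "counts": {
    "samples_received": {"value": 4871, "description": "cytology samples received for testing"},
    "patients": {"value": 4633, "description": "unique patients in the cohort"},
    "received_cb": {"value": 4588, "description": "samples received as cell-block preparations"},
    "received_scfdna": {"value": 283, "description": "samples received as supernatant cfDNA"},
    "canceled": {"value": 146, "description": "requests canceled before processing"},
    "sequenced_total": {"value": 4725, "description": "samples processed (received minus cancellations)"},
    "sequenced_cb": {"value": 4457, "description": "cell-block samples processed"},
    "sequenced_scfdna": {"value": 268, "description": "supernatant cfDNA samples processed"},
    "success_total": {"value": 3806, "description": "samples successfully sequenced and reported"},
    "success_cb": {"value": 3616, "description": "successful cell-block samples"},
    "success_scfdna": {"value": 190, "description": "successful supernatant cfDNA samples"},
    "contaminated_total": {"value": 246, "description": "samples with contamination >= 2%"},
    "contaminated_excl_very_low_cov": {"value": 227, "description": "contaminated samples after excluding <50x coverage failures"},
    "contaminated_cb": {"value": 226, "description": "contaminated cell-block samples (excluding <50x)"},
    "contaminated_scfdna": {"value": 1, "description": "contaminated supernatant cfDNA samples (excluding <50x)"},
    "cb_optimal_cov_contaminated": {"value": 189, "description": "cell-block samples >200x coverage with contamination above 2%"},
    "str_tracked": {"value": 65, "description": "contaminated samples traced to embedded foreign tissue by STR analysis"},
    "surgical_checked": {"value": 619, "description": "surgical comparison samples with contamination checks reviewed"},
    "surgical_contaminated": {"value": 5, "description": "surgical samples with clinically relevant contamination"},
    "alterations_total": {"value": 30149, "description": "somatic alterations detected across successful cases"},
    "cases_with_alteration": {"value": 3570, "description": "successful cases with at least one somatic alteration"},
    "alteration_cb": {"value": 3394, "description": "successful cell-block cases with at least one alteration"},
    "alteration_scfdna": {"value": 176, "description": "successful supernatant cfDNA cases with at least one alteration"},
    "targetable_cases": {"value": 2487, "description": "cases with at least one level 1/2/3A/3B alteration"},
    "resistance_cases": {"value": 93, "description": "cases with a standard-of-care resistance (R1) alteration"},
    "paired_cases": {"value": 526, "description": "cytology cases with a matched surgical sample"},
    "paired_cb": {"value": 482, "description": "matched pairs using a cell-block cytology sample"},
    "paired_scfdna": {"value": 44, "description": "matched pairs using a supernatant cfDNA sample"},
    "cb_pair_mutations": {"value": 5593, "description": "total mutations across the cell-block:surgical paired set"},
    "cb_pair_shared": {"value": 2789, "description": "mutations shared by both samples in the cell-block paired set"},
    "cb_pair_vus": {"value": 3468, "description": "no-level (VUS) mutations in the cell-block paired set"},
    "scfdna_pair_mutations": {"value": 692, "description": "total mutations across the supernatant cfDNA paired set"}
  },
  "metadata": {
    "median_coverage_x": 586,
    "median_coverage_cb_x": 595,
    "median_coverage_scfdna_x": 263,
    "median_dna_yield_cb_ng": 427.5,
    "median_dna_yield_scfdna_ng": 182.2,
    "copies_per_ng_mean": 238.0,
    "copies_per_ng_ci95_low": 220.5,
    "copies_per_ng_ci95_high": 255.5,
    "failure_percents_printed": {
      "fail_low_dna": 11.3,
      "fail_scant_tumor": 4.6,
      "fail_low_coverage": 1.8,
      "fail_contamination": 1.6,
      "fail_low_quality": 0.1
    },
    "note": "metadata values summarize protected per-sample distributions and cannot be recomputed from counts; they are carried for reference only"
  }
}
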