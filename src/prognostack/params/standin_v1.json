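{
  "format": "prognostack-params",
  "version": "standin-1.0",
  "comment": "Stand-in parameter set with plausible magnitudes and correct effect directions for a postmenopausal hormone-receptor-positive population. The published tool's coefficients are not printed in the literature this package draws on; every test and worked example in this repository is defined against this set. Externally published coefficient sets in the same JSON dialect can be loaded instead.",
  "basis": {
    "bc": ["intercept", "log", "p0.5"],
    "oth": ["intercept", "log", "p0.5"]
  },
  "mandatory_inputs": ["age", "size_mm", "nodes", "grade", "er_positive"],
  "parameters": [
    {"name": "bc_baseline_intercept", "group": "baseline_bc", "value": -6.213},
    {"name": "bc_baseline_logt",      "group": "baseline_bc", "value": 1.3},
    {"name": "bc_baseline_sqrt",      "group": "baseline_bc", "value": 0.0},
    {"name": "oth_baseline_intercept","group": "baseline_oth", "value": -5.637},
    {"name": "oth_baseline_logt",     "group": "baseline_oth", "value": 1.1},
    {"name": "oth_baseline_sqrt",     "group": "baseline_oth", "value": 0.0},
    {"name": "bc_age_fp1",            "group": "covariate_bc", "value": -6.88},
    {"name": "bc_age_fp2",            "group": "covariate_bc", "value": -10.0},
    {"name": "bc_log_size",           "group": "covariate_bc", "value": 0.80},
    {"name": "bc_log_nodes",          "group": "covariate_bc", "value": 0.55},
    {"name": "bc_grade2",             "group": "covariate_bc", "value": 0.45},
    {"name": "bc_grade3",             "group": "covariate_bc", "value": 1.00},
    {"name": "bc_er_negative",        "group": "covariate_bc", "value": 0.70},
    {"name": "bc_pr_negative",        "group": "covariate_bc", "value": 0.35},
    {"name": "bc_her2_positive",      "group": "covariate_bc", "value": 0.30},
    {"name": "bc_ki67_positive",      "group": "covariate_bc", "value": 0.20},
    {"name": "bc_screen_detected",    "group": "covariate_bc", "value": -0.25},
    {"name": "bc_micrometastases",    "group": "covariate_bc", "value": 0.15},
    {"name": "oth_age_dec",           "group": "covariate_oth", "value": 0.90},
    {"name": "oth_smoker",            "group": "covariate_oth", "value": 0.50},
    {"name": "oth_heart_dose",        "group": "covariate_oth", "value": 0.08},
    {"name": "oth_year_offset",       "group": "covariate_oth", "value": -0.01},
    {"name": "tx_chemotherapy",       "group": "treatment_effect", "value": -0.35},
    {"name": "tx_trastuzumab",        "group": "treatment_effect", "value": -0.20},
    {"name": "tx_radiotherapy",       "group": "treatment_effect", "value": -0.10},
    {"name": "tx_bisphosphonates",    "group": "treatment_effect", "value": -0.10}
  ]
}
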