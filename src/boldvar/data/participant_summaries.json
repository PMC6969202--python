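{
  "description": "Published per-group summary statistics (n, mean, SD) of the modelled cohort: 20 ASD and 17 typically developing boys. Used as inputs to recompute the group-difference tests; counts are handedness categories (RH/LH/mixed); correlations are published per-group Pearson r values with their sample sizes.",
  "groups": ["ASD", "TD"],
  "continuous": {
    "age": {"ASD": {"n": 20, "mean": 13.25, "sd": 2.87}, "TD": {"n": 17, "mean": 13.42, "sd": 3.21}},
    "iq": {"ASD": {"n": 20, "mean": 98.5, "sd": 14.33}, "TD": {"n": 17, "mean": 103.35, "sd": 10.15}},
    "fmri_mean_fd": {"ASD": {"n": 20, "mean": 0.106, "sd": 0.035}, "TD": {"n": 17, "mean": 0.096, "sd": 0.042}},
    "censored_timepoints": {"ASD": {"n": 20, "mean": 3.85, "sd": 1.69}, "TD": {"n": 17, "mean": 3.35, "sd": 1.84}},
    "dwi_mean_fd": {"ASD": {"n": 20, "mean": 0.609, "sd": 0.155}, "TD": {"n": 17, "mean": 0.546, "sd": 0.16}},
    "srs_total": {"ASD": {"n": 20, "mean": 104.25, "sd": 24.92}, "TD": {"n": 17, "mean": 18.41, "sd": 11.57}},
    "srs_awareness": {"ASD": {"n": 20, "mean": 13.1, "sd": 4.39}, "TD": {"n": 17, "mean": 3.82, "sd": 2.83}},
    "srs_cognition": {"ASD": {"n": 20, "mean": 17.85, "sd": 6.02}, "TD": {"n": 17, "mean": 2.94, "sd": 2.77}},
    "srs_communication": {"ASD": {"n": 20, "mean": 34.95, "sd": 10.36}, "TD": {"n": 17, "mean": 5.88, "sd": 4.48}},
    "srs_motivation": {"ASD": {"n": 20, "mean": 17.8, "sd": 4.12}, "TD": {"n": 17, "mean": 3.94, "sd": 2.44}},
    "srs_mannerisms": {"ASD": {"n": 20, "mean": 22.05, "sd": 7.86}, "TD": {"n": 17, "mean": 1.82, "sd": 2.77}}
  },
  "handedness": {"categories": ["RH", "LH", "mixed"], "ASD": [15, 3, 2], "TD": [14, 1, 2]},
  "correlation_comparisons": {
    "ge_age": {"r1": 0.46, "n1": 20, "r2": -0.32, "n2": 17},
    "mssd_brain_behavior_scores": {"r1": 0.6, "n1": 20, "r2": 0.38, "n2": 17},
    "entropy_brain_behavior_scores": {"r1": 0.67, "n1": 20, "r2": 0.5, "n2": 17}
  },
  "behavior_score_sds": {
    "mssd": {"ASD": {"n": 20, "sd": 1.18}, "TD": {"n": 17, "sd": 0.94}},
    "entropy": {"ASD": {"n": 20, "sd": 1.23}, "TD": {"n": 17, "sd": 0.93}}
  }
}
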