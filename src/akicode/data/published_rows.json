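{
  "description": "Printed diagnostic-performance rows (percent, one decimal) from the published ICD-10 N17x validation in kidney transplant recipients, with the cohort marginals needed to reconstruct the latent 2x2 counts. The main_diagnosis/stage_ge1 row was suppressed in the publication and is absent.",
  "n_total": 524,
  "reference_positive": {"stage_ge1": 236, "stage_ge2": 76, "stage_eq3": 55},
  "code_positive": {"any_diagnosis": 74, "admission_diagnosis": 54, "main_diagnosis": 25},
  "rows": [
    {"algorithm": "any_diagnosis", "reference": "stage_ge1",
     "sn": 28.0, "sn_lo": 22.6, "sn_hi": 34.0,
     "sp": 97.2, "sp_lo": 94.6, "sp_hi": 98.6,
     "ppv": 89.2, "ppv_lo": 80.1, "ppv_hi": 94.4,
     "npv": 62.2, "npv_lo": 57.7, "npv_hi": 66.6,
     "lr_plus": 10.0},
    {"algorithm": "any_diagnosis", "reference": "stage_ge2",
     "sn": 42.1, "sn_lo": 31.7, "sn_hi": 53.3,
     "sp": 90.6, "sp_lo": 87.6, "sp_hi": 93.0,
     "ppv": 43.2, "ppv_lo": 32.6, "ppv_hi": 54.6,
     "npv": 90.2, "npv_lo": 87.1, "npv_hi": 92.6,
     "lr_plus": 4.5},
    {"algorithm": "any_diagnosis", "reference": "stage_eq3",
     "sn": 40.0, "sn_lo": 28.1, "sn_hi": 53.2,
     "sp": 88.9, "sp_lo": 85.8, "sp_hi": 91.4,
     "ppv": 29.7, "ppv_lo": 20.5, "ppv_hi": 40.9,
     "npv": 92.7, "npv_lo": 89.9, "npv_hi": 94.7,
     "lr_plus": 3.6},
    {"algorithm": "admission_diagnosis", "reference": "stage_ge1",
     "sn": 20.3, "sn_lo": 15.7, "sn_hi": 25.9,
     "sp": 97.9, "sp_lo": 95.5, "sp_hi": 99.0,
     "ppv": 88.9, "ppv_lo": 77.8, "ppv_hi": 94.8,
     "npv": 60.0, "npv_lo": 55.5, "npv_hi": 64.3,
     "lr_plus": 9.7},
    {"algorithm": "admission_diagnosis", "reference": "stage_ge2",
     "sn": 34.2, "sn_lo": 24.5, "sn_hi": 45.4,
     "sp": 93.8, "sp_lo": 91.1, "sp_hi": 95.6,
     "ppv": 48.2, "ppv_lo": 35.4, "ppv_hi": 61.2,
     "npv": 89.4, "npv_lo": 86.3, "npv_hi": 91.8,
     "lr_plus": 5.5},
    {"algorithm": "admission_diagnosis", "reference": "stage_eq3",
     "sn": 32.7, "sn_lo": 21.8, "sn_hi": 45.9,
     "sp": 92.3, "sp_lo": 89.6, "sp_hi": 94.4,
     "ppv": 33.3, "ppv_lo": 22.2, "ppv_hi": 46.6,
     "npv": 92.1, "npv_lo": 89.3, "npv_hi": 94.2,
     "lr_plus": 4.2},
    {"algorithm": "main_diagnosis", "reference": "stage_ge2",
     "sn": 17.1, "sn_lo": 10.3, "sn_hi": 27.1,
     "sp": 97.3, "sp_lo": 95.4, "sp_hi": 98.5,
     "ppv": 52.0, "ppv_lo": 33.5, "ppv_hi": 70.0,
     "npv": 87.4, "npv_lo": 84.2, "npv_hi": 90.0,
     "lr_plus": 6.3},
    {"algorithm": "main_diagnosis", "reference": "stage_eq3",
     "sn": 18.2, "sn_lo": 10.2, "sn_hi": 30.3,
     "sp": 96.8, "sp_lo": 94.8, "sp_hi": 98.1,
     "ppv": 40.0, "ppv_lo": 23.4, "ppv_hi": 59.3,
     "npv": 91.0, "npv_lo": 88.2, "npv_hi": 93.2,
     "lr_plus": 5.7}
  ],
  "descriptives": {
    "any_aki_pct": 45.0,
    "stage_counts": {"0": 288, "1": 160, "2": 21, "3": 55},
    "code_positive_pct_any_diagnosis": 14.1,
    "stage1_share_of_aki_pct": 67.8,
    "baseline_scr_median": 133.0, "baseline_scr_q1": 103.0, "baseline_scr_q3": 173.9
  }
}
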