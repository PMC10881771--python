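{
  "description": "Extended Dujardin-style MR severity thresholds. Each grade owns a half-open interval [lo, hi) of regurgitant volume (ml) and regurgitant fraction (%); null means unbounded.",
  "grades": [
    {"grade": 0, "rvol_ml": [0, 12],  "rf_pct": [0, 19]},
    {"grade": 1, "rvol_ml": [12, 30], "rf_pct": [19, 30]},
    {"grade": 2, "rvol_ml": [30, 45], "rf_pct": [30, 40]},
    {"grade": 3, "rvol_ml": [45, 60], "rf_pct": [40, 50]},
    {"grade": 4, "rvol_ml": [60, null], "rf_pct": [50, null]}
  ]
}
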