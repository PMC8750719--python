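{
  "description": "Published prefactors of the correlations t_precool = A exp(0.002 d) and t_solidify = B exp(0.003 d) (d in micrometres), fitted to chamber-coupled 3-D CFD runs. Reference output for side-by-side reporting; a fixed-ambient lumped model is not expected to reproduce them.",
  "rate_precool_per_um": 0.002,
  "rate_solidify_per_um": 0.003,
  "rows": [
    {"Ta_K": 270.0, "Vdg_cm_s": 100.0, "A_s": 0.38, "B_s": 0.86},
    {"Ta_K": 270.0, "Vdg_cm_s": 20.0, "A_s": 0.5, "B_s": 1.25},
    {"Ta_K": 220.0, "Vdg_cm_s": 100.0, "A_s": 0.12, "B_s": 0.15},
    {"Ta_K": 220.0, "Vdg_cm_s": 20.0, "A_s": 0.21, "B_s": 0.23}
  ]
}
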