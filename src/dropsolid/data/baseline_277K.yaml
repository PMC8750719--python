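# Single 2 mm cocoa butter droplet in a 277 K / 1 bar chamber with an
# 83 cm/s air stream. Ambient lies inside the freezing window, so the
# droplet never fully solidifies; the run ends within 0.5 K of ambient.
material: cocoa_butter
droplet:
  d_m: 2.0e-3
  T_init_K: 318.0
ambient:
  Ta_K: 277.0
  p_Pa: 1.0e+5
  Vdg_m_s: 0.83
solver:
  epsilon_end_K: 0.5
  t_max_s: 600.0
  sample_interval_s: 0.05
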