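# Same droplet and flow as the baseline scenario but with a 263 K
# ambient: the droplet fully solidifies (~38 s) and then tempers.
material: cocoa_butter
droplet:
  d_m: 2.0e-3
  T_init_K: 318.0
ambient:
  Ta_K: 263.0
  p_Pa: 1.0e+5
  Vdg_m_s: 0.83
solver:
  epsilon_end_K: 0.5
  t_max_s: 600.0
  sample_interval_s: 0.05
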