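# The standard parametric grid: 4 diameters x 2 ambient temperatures x
# 2 relative drop-gas speeds, initial temperature 318 K at 1 bar.
d_um: [200.0, 300.0, 400.0, 500.0]
Ta_K: [220.0, 270.0]
Vdg_cm_s: [20.0, 100.0]
T_init_K: 318.0
p_Pa: 1.0e+5
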