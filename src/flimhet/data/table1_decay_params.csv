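setting,cell_line,tau_m,tau1,tau2,a1,bi_tau_m
in_vitro,HT29,0.80,0.39,2.47,80.11,1.05
in_vitro,HCT116,0.71,0.40,2.39,84.13,0.90
in_vitro,CaCo2,0.95,0.38,2.53,73.48,1.30
in_vitro,CT26,0.57,0.35,2.03,86.48,1.28
in_vivo,HT29,0.84,0.46,2.66,81.54,0.85
in_vivo,HCT116,0.88,0.47,2.66,80.61,0.91
in_vivo,CaCo2,1.02,0.42,2.91,76.89,1.51
in_vivo,CT26,0.72,0.39,2.34,82.12,1.20
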