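cell_line,bi_a1_mean,bi_a1_sd,d_a1
HT29,1.2,0.32,3.20
HCT116,0.93,0.23,2.60
CaCo2,0.86,0.15,4.00
CT26,1.06,0.54,2.81
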