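cell_line,bi_a1,d_a1
HT29,0.16,1.83
HCT116,0.92,2.01
CaCo2,0.49,3.41
CT26,0.63,1.67
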