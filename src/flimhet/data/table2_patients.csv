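sample,bi_a1,d_a1
1,1.25,7.77
2,0.81,4.18
3,1.01,8.68
4,1.16,11.99
5,1.01,6.93
6,1.00,7.83
7,0.86,9.33
8,0.70,8.25
9,1.28,11.51
10,1.25,6.96
11,0.59,4.5
12,1.45,2.37
13,1.34,4.94
14,1.05,2.19
15,0.89,4.16
16,0.24,3.34
17,1.29,6.10
18,1.32,5.41
19,0.80,2.23
20,0.94,5.19
21,1.28,5.27
22,0.98,3.29
23,1.53,6.54
24,1.31,5.77
25,0.88,4.87
26,1.58,5.83
27,1.65,4.14
28,0.5,5.67
29,1.29,6.36
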