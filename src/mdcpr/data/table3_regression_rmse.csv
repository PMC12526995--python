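subject,case1,case2,case3
1,0.479,0.318,0.647
2,0.552,0.452,0.392
3,0.567,0.799,0.723
4,0.365,0.572,0.752
5,0.412,0.727,0.241
6,0.510,0.649,0.364
7,0.753,0.389,0.612
8,0.412,0.643,0.530
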