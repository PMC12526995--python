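subject,case1,case2,case3
1,0.458,0.363,0.526
2,0.089,0.455,0.621
3,0.455,0.567,0.371
4,0.330,0.680,0.559
5,0.279,0.426,0.447
6,0.505,0.477,0.271
7,0.578,0.316,0.447
8,0.561,0.300,0.653
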