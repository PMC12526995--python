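subject,case1,case2,case3
1,0.474,0.697,0.909
2,0.410,1.250,1.046
3,0.598,0.725,1.353
4,0.519,0.962,1.422
5,0.938,0.686,1.440
6,0.670,0.826,1.309
7,0.446,0.668,1.501
8,0.409,0.653,1.457
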