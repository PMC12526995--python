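subject,case1,case2,case3
1,0.366,0.654,0.664
2,0.481,0.471,0.565
3,0.260,0.800,0.515
4,0.527,0.443,0.483
5,0.356,0.693,0.277
6,0.411,0.313,0.409
7,0.356,0.424,0.455
8,0.786,0.691,0.720
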