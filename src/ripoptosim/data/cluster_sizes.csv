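size_trimers,probability
1,0.38
2,0.19
3,0.12
4,0.085
5,0.065
6,0.045
7,0.03
8,0.02
12,0.03
16,0.02
20,0.015
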