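score,logit
0,-4.31
5,-1.90
10,-1.03
15,-0.43
20,0.07
25,0.55
30,1.07
35,1.82
40,4.01
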