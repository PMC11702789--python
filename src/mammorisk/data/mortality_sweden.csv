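age_lo,age_hi,rate
30,34,0.0006
35,39,0.0008
40,44,0.0011
45,49,0.0017
50,54,0.0026
55,59,0.0040
60,64,0.0062
65,69,0.0090
70,74,0.0145
75,79,0.0240
80,84,0.0420
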