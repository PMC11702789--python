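age_lo,age_hi,rate
30,34,0.0008
35,39,0.0010
40,44,0.0013
45,49,0.0020
50,54,0.0030
55,59,0.0045
60,64,0.0070
65,69,0.0100
70,74,0.0160
75,79,0.0260
80,84,0.0450
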