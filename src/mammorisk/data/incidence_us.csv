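age_lo,age_hi,rate
30,34,0.0003
35,39,0.0006
40,44,0.0012
45,49,0.0019
50,54,0.0022
55,59,0.0026
60,64,0.0031
65,69,0.0035
70,74,0.0036
75,79,0.0037
80,84,0.0036
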