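age_lo,age_hi,sex,utility
35,49,male,0.87
50,59,male,0.84
60,69,male,0.8
70,79,male,0.77
80,115,male,0.72
35,49,female,0.85
50,59,female,0.82
60,69,female,0.78
70,79,female,0.74
80,115,female,0.69
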