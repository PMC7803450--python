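age_lo,age_hi,factor
40,59,0.95
60,69,1.0
70,115,1.05
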