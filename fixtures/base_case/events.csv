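age_lo,age_hi,sex,stable_angina,unstable_angina,mi,stroke,tia,heart_failure,fatal_cvd
40,59,male,0.2,0.1,0.3,0.16,0.1,0.04,0.1
60,74,male,0.16,0.09,0.25,0.22,0.11,0.07,0.1
75,115,male,0.1,0.07,0.2,0.26,0.12,0.12,0.13
40,59,female,0.22,0.1,0.2,0.22,0.12,0.04,0.1
60,74,female,0.18,0.09,0.17,0.26,0.13,0.07,0.1
75,115,female,0.11,0.07,0.14,0.29,0.13,0.13,0.13
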