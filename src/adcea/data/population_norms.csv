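age_lower,utility
0,0.87
65,0.84
75,0.80
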