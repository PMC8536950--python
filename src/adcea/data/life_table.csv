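age_lower,sex,annual_q
50,female,0.003965
55,female,0.006064
60,female,0.009276
65,female,0.014188
70,female,0.021702
75,female,0.033195
80,female,0.050775
85,female,0.077665
90,female,0.118795
95,female,0.181708
100,female,0.277939
105,female,0.425133
110,female,0.650000
50,male,0.005815
55,male,0.008894
60,male,0.013604
65,male,0.020809
70,male,0.031830
75,male,0.048686
80,male,0.074470
85,male,0.113908
90,male,0.174233
95,male,0.266506
100,male,0.407644
105,male,0.623529
110,male,0.650000
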