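age_band,population
0-4,8180
5-9,8338
10-14,8497
15-19,8655
20-24,8814
25-29,8972
30-34,9130
35-39,9289
40-44,9400
45-49,8651
50-54,7616
55-59,6581
60-64,5546
65-69,4511
70-74,3476
75-79,2441
80-84,1406
85+,784
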