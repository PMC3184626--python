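sex,age_band,n,frac_discontinued,median_illness_months
male,18-21,26,0.40,21
male,22-29,72,0.48,30
male,30-39,128,0.53,72
male,40-49,127,0.56,60
male,50-59,116,0.65,48
male,60-64,32,0.59,31
female,18-21,150,0.25,36
female,22-29,294,0.43,26
female,30-39,461,0.43,36
female,40-49,411,0.53,48
female,50-59,281,0.61,55
female,60-64,72,0.60,87
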