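sex,age_band,mean_annual_income,pct_population,uk_population_thousands
male,18-21,11546,,
male,22-29,23460,655664,5135
male,30-39,35172,554200,4069
male,40-49,39390,535400,4523
male,50-59,36590,414100,3690
male,60-64,26505,190800,1818
female,18-21,8875,,
female,22-29,18508,638346,4922
female,30-39,22047,548400,4086
female,40-49,20880,541600,4631
female,50-59,19893,423200,3796
female,60-64,13662,200000,1901
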