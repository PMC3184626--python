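sex,mean_fraction,ci_low,ci_high,n
male,0.52,0.38,0.66,22
female,0.47,0.35,0.59,38
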