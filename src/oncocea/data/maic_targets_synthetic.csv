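covariate,target_value
age,57.5
male,0.62
ecog1,0.76
histology_adeno,0.95
liver_met,0.58
prior_lines_ge2,0.68
prior_targeted,0.45
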