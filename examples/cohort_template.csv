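participant_id,group,amputation_level,side,deprivation_age,cosmetic_prosthesis_usage,functional_prosthesis_usage,mal_score,pain_intensity,pain_frequency,laterality_index,beta_intact_hand,beta_residual_arm
A01,acquired,4,L,38,2,0,0.35,5,2,0.82,1.12,0.21
C01,congenital,4,R,0,5,0,0.72,0,5,0.41,0.33,0.95
H01,control,,,,,,,,,,0.52,0.48
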