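study_id,population,country,sample_type,n,smoker_status,mean,sd,median,p95,max,min,unit,lod_censored
labat,worker,France,post_shift_spot,13,unspecified,523,321.6,,962,984.1,,ug_per_L,True
korinth,worker,Germany,post_shift_spot,51,unspecified,38.6,,,292.4,292.4,,ug_per_L,True
li,worker,Sweden,post_shift_spot,157,unspecified,,,0.46,,108,0.03,ug_per_L,False
eitaki,worker,Japan,post_shift_spot,36,unspecified,55.5,,,,129.12,,ug_per_L,True
seidel,general,Germany,urine_24h,81,non_smoker,,,61.8,,401,,ng_per_24h,False
riedel_nonsmoker,general,Germany,urine_24h,10,non_smoker,167,199.4,,,,,ng_per_24h,False
riedel_smoker,general,Germany,urine_24h,10,smoker,204.2,59.1,,,,,ng_per_24h,False
lindner_nonsmoker,general,Germany/Switzerland/UK,urine_24h,408,non_smoker,64,128,,,,,ng_per_24h,False
lindner_smoker,general,Germany/Switzerland/UK,urine_24h,1223,smoker,179,497,,,,,ng_per_24h,False
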