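study,aa,value,sd,n_subjects,body_weight,unit
study_a,histidine,297.0,44.55,12,75.0,mg_per_day
study_b,histidine,222.75,33.4125,24,75.0,mg_per_day
study_a,isoleucine,27.0,4.05,12,75.0,mg_per_day
study_b,isoleucine,20.25,3.0375,24,75.0,mg_per_day
study_a,leucine,36.0,5.4,12,75.0,mg_per_day
study_b,leucine,27.0,4.05,24,75.0,mg_per_day
study_a,lysine,90.0,13.5,12,75.0,mg_per_day
study_b,lysine,67.5,10.125,24,75.0,mg_per_day
study_a,methionine,45.0,6.75,12,75.0,mg_per_day
study_b,methionine,33.75,5.0625,24,75.0,mg_per_day
study_a,cysteine,63.0,9.45,12,75.0,mg_per_day
study_b,cysteine,47.25,7.0875,24,75.0,mg_per_day
study_a,phenylalanine,54.0,8.1,12,75.0,mg_per_day
study_b,phenylalanine,40.5,6.075,24,75.0,mg_per_day
study_a,tyrosine,63.0,9.45,12,75.0,mg_per_day
study_b,tyrosine,47.25,7.0875,24,75.0,mg_per_day
study_a,threonine,81.0,12.15,12,75.0,mg_per_day
study_b,threonine,60.75,9.1125,24,75.0,mg_per_day
study_a,tryptophan,54.0,8.1,12,75.0,mg_per_day
study_b,tryptophan,40.5,6.075,24,75.0,mg_per_day
study_a,valine,27.0,4.05,12,75.0,mg_per_day
study_b,valine,20.25,3.0375,24,75.0,mg_per_day
study_a,alanine,99.0,14.85,12,75.0,mg_per_day
study_b,alanine,74.25,11.1375,24,75.0,mg_per_day
study_a,arginine,36.0,5.4,12,75.0,mg_per_day
study_b,arginine,27.0,4.05,24,75.0,mg_per_day
study_a,aspartate,90.0,13.5,12,75.0,mg_per_day
study_b,aspartate,67.5,10.125,24,75.0,mg_per_day
study_a,asparagine,216.0,32.4,12,75.0,mg_per_day
study_b,asparagine,162.0,24.3,24,75.0,mg_per_day
study_a,glutamate,402.93,60.4395,12,75.0,mg_per_day
study_b,glutamate,302.1975,45.3296,24,75.0,mg_per_day
study_a,glycine,1080.0,162.0,12,75.0,mg_per_day
study_b,glycine,810.0,121.5,24,75.0,mg_per_day
study_a,proline,72.0,10.8,12,75.0,mg_per_day
study_b,proline,54.0,8.1,24,75.0,mg_per_day
study_a,serine,144.0,21.6,12,75.0,mg_per_day
study_b,serine,108.0,16.2,24,75.0,mg_per_day
reference_range,glutamine,100.0,15.0,30,75.0,mmol_per_mol_creatinine
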