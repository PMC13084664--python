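metabolite,parent_aa,excretion,sd,stoichiometry,unit
3-methylhistidine,histidine,2.900419e-04,9.668063e-05,1.0,mol_per_day
hydroxylysine,lysine,1.026062e-04,2.052124e-05,1.0,mol_per_day
taurine,methionine,5.026473e-04,4.523825e-04,1.0,mol_per_day
cystathionine,methionine,1.507942e-04,1.507942e-04,1.0,mol_per_day
catecholamine metabolites,tyrosine,4.139301e-05,1.241790e-05,1.0,mol_per_day
5-hydroxyindoleacetic acid,tryptophan,7.344660e-05,1.468932e-05,1.0,mol_per_day
kynurenine metabolites,tryptophan,3.672330e-05,1.101699e-05,1.0,mol_per_day
beta-aminoisobutyrate,aspartate,1.690458e-04,5.634861e-05,1.0,mol_per_day
creatinine,glycine,1.500000e-02,1.798322e-03,1.0,mol_per_day
uric acid,glycine,2.183962e-03,1.398695e-03,1.0,mol_per_day
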