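source,aa_code,mmd_ratio,fao_ratio
whole_milk,His,0.77,1.84
whole_egg,His,0.5,1.19
beef,His,1.02,2.44
soy_protein_isolate,His,0.63,1.6
rice,His,0.54,1.3
mung_bean,His,0.68,1.62
whole_milk,Ile,1.2,1.32
whole_egg,Ile,1.25,1.38
beef,Ile,1.56,1.72
soy_protein_isolate,Ile,1.07,1.27
rice,Ile,1.03,1.13
mung_bean,Ile,1.01,1.11
whole_milk,Leu,1.4,1.5
whole_egg,Leu,1.14,1.21
beef,Leu,1.33,1.42
soy_protein_isolate,Leu,1.1,1.25
rice,Leu,1.13,1.21
mung_bean,Leu,1.0,1.07
whole_milk,Lys,1.34,1.72
whole_egg,Lys,1.06,1.37
beef,Lys,1.52,1.96
soy_protein_isolate,Lys,0.97,1.24
rice,Lys,0.48,0.62
mung_bean,Lys,0.9,1.17
whole_milk,SAA,0.69,1.28
whole_egg,SAA,0.88,1.64
beef,SAA,1.04,1.94
soy_protein_isolate,SAA,0.5,1.0
rice,SAA,0.88,1.64
mung_bean,SAA,0.28,0.52
whole_milk,AAA,1.4,2.43
whole_egg,AAA,1.17,2.03
beef,AAA,1.16,2.01
soy_protein_isolate,AAA,1.22,2.24
rice,AAA,1.39,2.42
mung_bean,AAA,1.12,1.95
whole_milk,Thr,0.68,1.7
whole_egg,Thr,0.66,1.66
beef,Thr,0.74,1.87
soy_protein_isolate,Thr,0.56,1.52
rice,Thr,0.55,1.39
mung_bean,Thr,0.4,1.0
whole_milk,Trp,0.78,1.69
whole_egg,Trp,0.74,1.61
beef,Trp,0.92,1.98
soy_protein_isolate,Trp,0.88,2.0
rice,Trp,0.94,2.04
mung_bean,Trp,0.55,1.2
whole_milk,Val,1.06,1.28
whole_egg,Val,0.99,1.19
beef,Val,1.25,1.51
soy_protein_isolate,Val,0.79,1.03
rice,Val,0.98,1.18
mung_bean,Val,0.83,1.01
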