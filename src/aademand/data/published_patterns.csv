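aa_code,mmd_pattern_mg_per_g,fao_pattern_mg_per_g
His,36,15
Ile,33,30
Leu,63,59
Lys,58,45
SAA,41,22
AAA,66,38
Thr,58,23
Trp,13,6
Val,47,39
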