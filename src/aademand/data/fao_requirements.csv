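key,requirement_mg_per_kg_d
protein,660.0
His,10.0
Ile,20.0
Leu,39.0
Lys,30.0
SAA,15.0
AAA,25.0
Thr,15.0
Trp,4.0
Val,26.0
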