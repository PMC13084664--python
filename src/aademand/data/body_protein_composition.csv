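aa_code,mg_per_g,synthetic
His,27,0
Ile,35,0
Leu,75,0
Lys,73,0
SAA,35,0
AAA,73,0
Thr,42,0
Trp,12,0
Val,49,0
Ala,65,1
Arg,69,1
Asx,93,1
Glx,128,1
Gly,103,1
Pro,75,1
Ser,46,1
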