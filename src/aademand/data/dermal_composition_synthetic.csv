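aa_code,mg_per_g
His,29.8125
Ile,25.3125
Leu,47.8125
Lys,58.9375
SAA,85.3125
AAA,33.9375
Thr,51.375
Trp,8.25
Val,42.4375
Ala,38.4375
Arg,201.1875
Asx,42.6875
Glx,88.0
Gly,102.0625
Pro,42.8125
Ser,104.125
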