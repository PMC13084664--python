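aa_code,class,pto_pp_mean,pto_pp_sd,pto_pa_mean,pto_pa_sd,egl_mean,egl_sd,ufaap_mean,ufaap_sd,hsnm_mean,hsnm_sd,ol_mean,ol_sd,io_sd_override,mmd_published,mmd_sd_published
His,IAA,1.7,1.4,4.2,0.8,5.3,1.2,3.3,0.67,0.9,0.2,0.6,0.2,0.5,22.5,2.1
Ile,IAA,2.2,1.8,5.4,1.0,6.4,0.9,0.3,0.02,0.9,0.2,0.0,0.0,0.4,21.4,2.3
Leu,IAA,4.7,3.9,11.6,2.1,9.7,1.3,0.4,0.05,1.8,0.3,0.0,0.0,0.8,39.7,4.6
Lys,IAA,4.5,3.8,11.3,2.1,7.1,0.8,1.0,0.2,2.0,0.4,0.2,0.04,0.7,36.8,4.4
SAA,IAA,2.2,1.8,5.4,1.0,6.4,0.4,1.2,0.3,2.1,0.4,1.3,1.0,0.5,26.3,2.4
AAA,IAA,4.5,3.8,11.3,2.1,10.7,1.8,1.3,0.2,1.5,0.3,0.1,0.03,0.8,41.6,4.7
Thr,IAA,2.6,2.2,6.5,1.2,14.5,1.9,0.9,0.1,1.5,0.3,0.0,0.0,0.7,36.6,3.1
Trp,IAA,0.7,0.6,1.9,0.3,1.5,0.1,0.6,0.1,0.3,0.1,0.3,0.05,0.2,7.5,0.7
Val,IAA,3.0,2.5,7.6,1.4,8.8,0.8,0.3,0.1,1.4,0.2,0.0,0.0,0.6,29.8,3.0
Ala,DAA,4.2,3.5,10.5,1.9,7.1,0.7,1.1,0.4,1.5,0.3,0.0,0.0,0.7,34.5,4.1
Arg,DAA,4.5,3.7,11.2,2.0,5.0,0.3,0.4,0.1,4.8,0.9,0.0,0.0,0.7,36.3,4.3
Asx,DAA,5.3,4.4,13.2,2.4,15.0,1.1,3.4,0.3,1.9,0.3,0.3,0.1,1.1,55.0,5.2
Glx,DAA,7.6,6.4,19.1,3.5,16.6,3.2,7.4,1.4,3.2,0.6,0.0,0.0,1.5,75.8,8.1
Gly,DAA,6.9,5.7,17.2,3.1,11.7,3.0,12.0,2.7,3.2,0.6,17.2,2.3,1.9,96.0,8.0
Pro,DAA,4.9,4.1,12.3,2.2,10.7,0.9,0.8,0.3,1.7,0.3,0.0,0.0,0.9,42.8,4.8
Ser,DAA,2.5,2.1,6.4,1.2,9.2,1.3,1.6,0.5,2.6,0.5,0.0,0.0,0.6,31.4,2.8
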