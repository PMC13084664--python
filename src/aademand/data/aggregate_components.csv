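target,io_mean,io_sd,pto_pp_mean,pto_pp_sd,pto_pa_mean,pto_pa_sd,egl_mean,egl_sd,ufaap_mean,ufaap_sd,hsnm_mean,hsnm_sd,ol_mean,ol_sd,mmd_published,mmd_sd_published
total_protein,183.9,12.7,62.2,51.8,155.1,28.2,145.6,19.6,35.9,3.7,31.3,5.6,20.1,2.7,634.1,62.6
total_iaa,76.1,5.2,26.2,21.8,65.3,11.9,70.1,9.0,9.4,0.8,12.4,2.2,2.6,1.0,262.3,26.5
total_daa,107.8,7.4,36.0,30.0,89.8,16.3,75.5,10.7,26.6,3.6,18.8,3.4,17.5,2.3,371.8,36.2
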