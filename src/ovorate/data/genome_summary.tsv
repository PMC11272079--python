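quantity	value
n_genes	9232
m0_dn_p95	0.235
m0_ds_p95	0.791
possel_freq_Dsim	0.054
possel_freq_Dsec	0.120
possel_freq_Dmel	0.041
hawaiian_median_Dmur	0.152
hawaiian_median_Dspr	0.164
hawaiian_median_Dgri	0.160
hawaiian_ovarioles_Dspr	65.6
hawaiian_ovarioles_Dmur	41.6
hawaiian_ovarioles_Dgri	47.8
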