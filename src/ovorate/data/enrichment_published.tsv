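label	gene_set	branch	k	n	p0	yates	printed_p
dsec_signalc	SIGNALC_27	Dsec	6	27	0.12	False	0.05
dsim_sh_exclusive	SH_exclusive_8	Dsim	2	8	0.054	True	0.047
dsec_tf_exclusive	TF_exclusive_26	Dsec	6	26	0.12	True	0.077
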