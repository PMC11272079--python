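gene_id	symbol	dataset	pgls_p	intercept	slope	pred_Dsim	pred_Dsec	pred_Dmel	pred_Dyak	pred_Dere
FBgn0011274	Dif	SIGNALC	0.0189	38.0298	-25.8738	38.03	22.55	38.03	19.32	27.30
FBgn0003612	Su(var)2-10	SIGNALC	0.0115	22.0048	28.8688	38.53	22.01	37.83	23.92	22.36
FBgn0011642	Zyx	SIGNALC	0.0205	35.9756	-14.2358	31.56	14.62	31.88	32.18	31.39
FBgn0004858	elB	SIGNALC	0.0170	32.7685	-28.2679	32.77	15.36	31.93	30.90	31.02
FBgn0259176	bun	SIGNALC	0.0316	43.5717	-83.9484	38.02	22.01	35.10	28.34	20.77
FBgn0023540	CG3630	SIGNALC	0.0689	41.6675	-46.7838	24.90	13.89	35.83	30.49	36.39
FBgn0030904	upd2	SIGNALC	0.0143	34.3707	-42.2274	34.37	16.77	32.91	31.02	27.33
FBgn0003607	Su(var)205	SIGNALC	0.0092	18.0230	120.0788	31.26	18.04	43.32	24.99	25.64
FBgn0261592	RpS6	SIGNALC	0.0261	31.9450	-55.4869	31.94	15.01	30.95	31.94	31.94
FBgn0032006	Pvr	SIGNALC	0.0162	38.4848	-71.3851	37.94	20.64	34.67	26.96	23.76
FBgn0045035	tefu	SIGNALC	0.0520	49.0222	-158.1686	35.29	18.84	29.69	32.40	26.70
FBgn0051157	CG31157	BULKSG	0.0175	34.6446	-14.4238	32.97	15.56	31.81	29.73	32.08
FBgn0044048	Ilp5	BULKSG	0.0225	44.4030	-40.6225	32.49	20.67	44.40	24.47	22.06
FBgn0015872	Drip	BULKSG_SINGLEC	0.0474	38.3688	-16.6128	27.99	13.45	31.49	32.14	36.19
FBgn0040343	CG3713	BULKSG_SINGLEC	0.0470	22.8789	10.9136	39.25	22.88	31.86	24.52	26.40
FBgn0016075	vkg	BULKSG_SINGLEC	0.0171	45.3114	-37.1647	34.02	17.23	34.29	32.27	24.60
FBgn0000299	Col4a1	BULKSG_SINGLEC	0.0053	39.2022	-18.3941	33.62	16.17	35.39	30.51	26.55
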