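gene_id	symbol	source	m0_omega	Dsim	Dsec	Dmel	Dyak	Dere	tau
FBgn0011274	Dif	SIGNALC		0.0001	0.5981	0.0001	0.7233	0.4146	
FBgn0014020	Rho1	SIGNALC		-	0.0001	-	0.0001	-	
FBgn0003612	Su(var)2-10	SIGNALC		0.5723	0.0001	0.5482	0.0662	0.0122	
FBgn0026379	Pten	SIGNALC		0.0001	0.1773	0.3122	0.1278	0.5944	
FBgn0000259	CkIIbeta	SIGNALC		0.6516	0.2694	0.0001	0.0001	0.0001	
FBgn0035213	CG2199	SIGNALC		1.0905	0.404	0.3582	0.328	0.2765	
FBgn0011642	Zyx	SIGNALC		0.3100	>1	0.2877	0.2668	0.3222	
FBgn0262614	pyd	SIGNALC		0.0165	0.0341	0.4745	0.0168	0.0969	
FBgn0036974	eRF1	SIGNALC		0.0001	0.1445	0.3901	0.0001	0.0697	
FBgn0003984	vn	SIGNALC		0.4712	0.2069	0.0841	0.2802	0.1511	
FBgn0004858	elB	SIGNALC		0.0001	0.6159	0.0297	0.066	0.0617	
FBgn0010825	Gug	SIGNALC		0.5467	0.3674	0.0539	0.0469	0.0416	
FBgn0002174	CG5504	SIGNALC		0.2527	0.3135	0.0423	0.0812	0.0937	
FBgn0037218	aux	SIGNALC		0.0648	0.1874	0.1639	0.2738	0.2413	
FBgn0259176	bun	SIGNALC		0.0661	0.2569	0.1009	0.1814	0.2716	
FBgn0023540	CG3630	SIGNALC		0.3585	0.5938	0.1247	0.239	0.1129	
FBgn0261854	aPKC	SIGNALC		0.1931	0.0126	0.0001	0.0001	0.0855	
FBgn0001169	H	SIGNALC		0.1982	0.1646	0.1585	0.2220	0.1746	
FBgn0024291	Sirt1	SIGNALC		0.0001	0.1876	0.2589	0.1113	0.071	
FBgn0030904	upd2	SIGNALC		-	0.4168	0.0347	0.0793	0.1667	
FBgn0020496	CtBP	SIGNALC		0.5440	0.0001	0.0697	0.0001	0.1103	
FBgn0003607	Su(var)205	SIGNALC		0.1102	0.0001	0.2107	0.058	0.0634	
FBgn0261592	RpS6	SIGNALC		0.0001	0.3052	0.0179	0.0001	0.0001	
FBgn0020386	Pdk1	SIGNALC		0.3558	0.4589	0.0996	0.0624	0.0490	
FBgn0002592	E(spl)m2-BFM	SIGNALC		0.5554	0.2217	0.0197	0.1984	0.1469	
FBgn0032006	Pvr	SIGNALC		0.0077	0.2500	0.0535	0.1614	0.2063	
FBgn0045035	tefu	SIGNALC		0.0868	0.1908	0.1222	0.1051	0.1411	
FBgn0052581	CG32581	BULKSG	0.3052	0.1647	0.6899	0.5668	0.2455	0.1672	0.7378
FBgn0051157	CG31157	BULKSG	0.2962	0.1163	1.3228	0.1967	0.3405	0.1777	0.9010
FBgn0039108	CG10232	BULKSG	0.7202	>1	2.0881	0.4894	0.6514	0.5914	0.9260
FBgn0039598	aqrs	BULKSG	0.2305	0.1183	0.1097	0.1265	0.3029	0.1972	0.9946
FBgn0260479	CG31904	BULKSG	0.3038	0.0001	0.4808	0.6401	0.0556	0.1363	0.9466
FBgn0044048	Ilp5	BULKSG	0.3776	0.2932	0.5843	0.0001	0.4907	0.5501	0.8485
FBgn0031900	CG13786	BULKSG	0.2487	0.1709	0.2778	0.2748	0.2362	0.3271	0.9483
FBgn0050281	CG30281	BULKSG	0.2155	0.4796	0.613	0.1951	0.1806	0.249	0.9820
FBgn0031646	snsl	BULKSG	0.2672	0.1571	0.0635	0.1566	0.2317	0.585	0.9408
FBgn0051815	CG31815	BULKSG	0.3745	0.1725	0.3185	0.3421	0.4465	0.3695	0.9519
FBgn0015872	Drip	BULKSG_SINGLEC	0.2734	0.6248	>1	0.4140	0.3750	0.1312	0.9786
FBgn0040343	CG3713	BULKSG_SINGLEC	0.2636	>1	0.0001	0.8226	0.1501	0.3225	0.9146
FBgn0002868	MtnA	BULKSG_SINGLEC	0.6883	-	>1	>1	>1	0.1265	0.8753
FBgn0016075	vkg	BULKSG_SINGLEC	0.3860	0.3038	0.7557	0.2965	0.3510	0.5572	0.9037
FBgn0000299	Col4a1	BULKSG_SINGLEC	0.4065	0.3034	1.2519	0.2072	0.4728	0.6879	0.8887
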