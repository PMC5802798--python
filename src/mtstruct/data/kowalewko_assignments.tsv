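sample_id	haplogroup_score	haplogroup	anthropological_sex	genetic_sex
PCA0001	0.8	W	M	-
PCA0002	1	H28a1	M	-
PCA0003	1	H5a1	F	-
PCA0004	1	U3a1a1	F	-
PCA0005	-	U5b	M	-
PCA0006	1	U5a1d1	F	-
PCA0007	1	W1	F	-
PCA0013	1	J1c3	-	-
PCA0014	-	-	F	-
PCA0015	1	H1f1a	M	M
PCA0016	-	-	-	-
PCA0017	-	-	M	-
PCA0018	0.5	HV18	M	M
PCA0019	-	-	F	-
PCA0020	-	-	-	-
PCA0021	-	-	-	-
PCA0022	-	-	F	-
PCA0023	-	-	-	-
PCA0024	-	-	F	-
PCA0025	-	-	F	-
PCA0026	0.5	T2b16	F	F
PCA0027	1	H1a	M	M
PCA0028	1	U3a1a	F	F
PCA0029	1	X2c1	-	-
PCA0030	1	H2a2b	F	-
PCA0031	1	K2a	F	F
PCA0032	0.5	T2n	F	F
PCA0033	-	-	F	-
PCA0034	1	K2a	F	F
PCA0035	0.5	J2b1a5	M	M
PCA0036	1	U5b1d1	M	-
PCA0037	0.5	T2e	M	M
PCA0038	1	H1e1a	-	-
PCA0039	-	-	-	-
PCA0040	1	I4a	M	M
PCA0041	0.8	N	M	-
PCA0042	-	-	-	-
PCA0043	-	-	-	-
PCA0044	1	H5a1	F	F
PCA0045	1	U5b1d	F	F
PCA0046	1	U8a1a1b	M	M
PCA0047	1	H5a1	F	F
PCA0048	-	-	-	-
PCA0049	1	H1a	F	F
PCA0050	1	H1e1a	M	M
PCA0051	0.4	K2a	-	F
PCA0052	1	U5a1a1	F	F
PCA0053	1	K1b2a	F	F
PCA0054	1	U3a1a	-	F
PCA0055	-	-	-	-
PCA0056	1	T2b6a	F	F
PCA0057	1	J1c7a	F	-
PCA0058	-	-	-	-
PCA0059	1	K2a	F	F
PCA0060	1	U5b1d1	M	M
PCA0061	1	H1ak	-	-
PCA0062	1	U4a2	M	M
PCA0063	1	H2a5	M	M
PCA0064	-	-	F	-
PCA0066	1	H2a5	M	M
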