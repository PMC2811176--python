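position	iugr_mean	control_mean	difference	p_x1e6	CpG	CGc	phC	Rep	Loc	genes	refseq
chr2:235526053-235526128	2.06	2.66	-0.61	0.4	YES	YES	YES		PRO	SH3BP4	NM_014521
chrX:66138356-66139206	-0.78	-1.29	0.51	0.8	no	no	no	RT
chr15:45018938-45019873	-0.62	-1.11	0.48	0.9	no	no	YES
chr6:106879977-106880120	2.56	3.34	-0.78	1.1	YES	YES	YES		PRO	ATG5	NM_004849
chr18:18624869-18626554	-0.72	-1.28	0.55	1.3	no	no	YES
chr2:176841167-176842343	-0.16	-0.48	0.33	1.5	no	YES	no	LT	PRO	MTX2	NM_006554
chr6:113687585-113688546	-1.81	-2.61	0.80	1.5	no	no	YES
chr11:77123865-77124724	-0.60	-1.33	0.73	1.8	YES	no	YES		GB	RSF1	NM_016578
chrX:70857596-70857847	0.51	1.28	-0.77	2.0	no	no	no
chr19:2616301-2616955	-0.86	-1.18	0.32	2.2	no	no	no	RT	GB	GNG7	NM_052847
chr12:123573299-123573372	1.80	2.79	-1.00	2.2	no	no	no		PRO	NCOR2	NM_006312
chr4:102487593-102487694	1.59	2.55	-0.97	2.4	YES	YES	YES		PRO	PPP3CA	NM_000944
chr11:13612440-13613698	-1.01	-1.79	0.78	2.5	no	no	no
chr20:39422191-39423123	-0.42	-0.94	0.52	2.7	no	no	YES		GB	LPIN3 EMILIN3	NM_022896 NM_052846
chrX:48943071-48943319	1.94	2.72	-0.78	3.0	YES	YES	YES		PRO	SYP	NM_003179
chr12:105961981-105963288	-1.44	-2.49	1.06	3.1	no	no	no	RT	PRO	CRY1	NM_004075
chr11:76172201-76172653	2.48	3.16	-0.68	3.2	YES	YES	YES		PRO	TSKU	NM_015516
chr8:318760-319070	-1.07	-0.60	-0.47	3.4	no	no	no
chr8:25575968-25577680	-1.53	-2.41	0.88	3.4	no	no	YES
chrX:99552722-99552801	3.09	3.62	-0.52	3.7	YES	YES	YES		PRO	PCDH19	NM_020766
chr22:45949018-45950112	-1.23	-1.87	0.65	3.7	no	YES	no
chr11:99814353-99814807	-0.48	0.36	-0.83	3.8	no	no	no
chr15:91226882-91227081	2.40	3.34	-0.93	3.8	no	YES	YES
chr3:9809841-9809915	1.49	2.24	-0.74	3.8	YES	YES	YES		PRO2	TADA3L ARPC4	NM_006354 NM_005718
chr12:1774845-1774939	1.72	2.45	-0.73	4.2	no	no	no		GB	CACNA2D4	NM_172364
chr15:88120371-88120587	1.28	2.08	-0.79	4.4	YES	YES	YES		PRO	MESP2	NM_001039958
chr9:78132928-78133704	-0.91	-1.56	0.65	5.2	no	no	YES
chr9:33740402-33740551	1.61	2.41	-0.80	5.2	YES	YES	no		PRO	PRSS3	NM_007343
chr16:4746813-4747596	-1.50	-1.85	0.35	5.2	no	no	no	RT	GB	ZNF500	NM_021646
chr3:129693359-129693420	1.66	2.31	-0.65	5.2	YES	YES	no		PRO	GATA2	NM_032638
chr2:206657793-206657892	2.47	3.43	-0.96	5.4	no	YES	YES		PRO	INO80D	NM_017759
chr6:21543836-21545402	-1.61	-2.10	0.49	5.6	no	no	no	RT
chr22:16347210-16348259	-1.26	-1.62	0.36	5.9	no	no	no	RT	GB	CECR2	NM_031413
chr8:94370466-94372334	-1.26	-2.09	0.84	6.1	no	no	no
chr20:22581679-22582432	-1.09	-1.76	0.67	6.1	no	no	YES
chr21:25927844-25929694	-1.13	-1.77	0.64	6.3	no	no	YES	RT/LT
chr12:105841213-105843079	-1.42	-1.71	0.29	6.4	no	no	no	RT
chrX:39752669-39752723	1.04	1.99	-0.95	6.5	YES	YES	YES
chr16:87294955-87295022	1.03	1.63	-0.60	6.7	no	YES	no		GB	RNF166	NM_178841
chr22:17514809-17516325	2.52	3.26	-0.74	7.0	YES	YES	no		PRO	GSC2	NM_005315
chr15:78244066-78244975	-1.04	-1.49	0.45	7.1	no	no	no		GB	FAH	NM_000137
chr10:101825755-101826964	-1.72	-2.11	0.39	7.2	no	no	YES		PRO	CPN1	NM_001308
chr16:29563652-29563719	2.38	3.22	-0.83	7.3	no	no	no	RT
chr5:132564040-132565611	-1.89	-2.55	0.66	7.5	no	no	YES		PRO	FSTL4	NM_015082
chr18:40597598-40598729	-2.17	-2.86	0.69	7.6	no	no	YES		GB	SETBP1	NM_015559
chr17:17019265-17021036	-1.34	-1.94	0.60	7.9	no	no	YES		GB	MPRIP	NM_015134
chr4:101159747-101160275	-1.72	-2.38	0.66	8.0	no	no	no	RT
chr11:120258272-120258456	2.13	2.91	-0.78	8.1	no	no	YES		PRO	GRIK4	NM_014619
chr9:19033554-19034579	-0.19	-0.84	0.65	8.5	no	no	no	RT
chr8:59144552-59145204	-1.10	-1.61	0.52	8.6	no	no	YES		GB	FAM110B	NM_147189
chr6:41861921-41862019	0.99	1.56	-0.57	8.7	YES	YES	YES		GB	PRICKLE4	NM_013397
chr15:61088671-61090467	-0.44	-1.03	0.59	8.8	no	no	no
chr10:71811777-71811840	1.86	2.76	-0.90	8.8	YES	YES	no		PRO	LRRC20	NM_018205
chr12:109990645-109990725	1.32	2.32	-1.00	9.1	no	no	YES		PRO	CUX2	NM_015267
chr3:124611357-124611643	3.63	4.23	-0.61	9.4	no	no	YES		PRO	ADCY5	NM_183357
chr10:92344854-92345619	-1.70	-2.71	1.01	9.7	no	no	no
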