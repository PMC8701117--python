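probe_id	chrom	pos	gene	pair1	pair2	pair3	mean	p	irg	relation
cg13304609	1	79085162	IFI44L	-0.24	-0.27	-0.37	-0.29	1.58e-14	IRG
cg06872964	1	79085250	IFI44L		-0.26	-0.21	-0.24	1.05e-71	IRG
cg03607951	1	79085586	IFI44L	-0.27	-0.30	-0.21	-0.26	7.23e-22	IRG
cg17515347	1	159047163	AIM2	-0.09	-0.11	-0.07	-0.09	3.01e-12	IRG
cg08272268	1	200380059	ZNF281	-0.08	-0.07	-0.11	-0.09	4.33e-15		S_Shore
cg01028142	2	7004578	CMPK2	-0.22	-0.36	-0.43	-0.33	7.98e-8	IRG	N_Shore
cg10959651	2	7018020	RSAD2	-0.13	-0.10	-0.16	-0.13	3.14e-14	IRG
cg10549986	2	7018153	RSAD2	-0.08	-0.09	-0.10	-0.09	1.95e-91	IRG
cg14126601	2	37384708	EIF2AK2	-0.08	-0.10	-0.12	-0.10	5.55e-16	IRG	S_Shore
cg26337070	2	85999873	ATOH8	-0.06	-0.12	-0.11	-0.10	7.55e-9
cg04781494	2	202047246	CASP10	-0.07	-0.13	-0.08	-0.09	8.39e-8	IRG
cg15768138	2	219030752	CXCR1	-0.09	-0.12	-0.11	-0.11	7.38e-27
cg13411554	3	53700276	CACNA1D	-0.06	-0.12	-0.09	-0.09	8.66e-8
cg22930808	3	122281881	PARP9-DTX3L	-0.36	-0.34	-0.40	-0.37	6.74e-126	IRG	N_Shore
cg08122652	3	122281939	PARP9-DTX3L	-0.34	-0.31	-0.51	-0.38	1.11e-9	IRG	N_Shore
cg00959259	3	122281975	PARP9-DTX3L	-0.37	-0.30	-0.34	-0.34	1.32e-56	IRG	N_Shore
cg06981309	3	146260954	PLSCR1	-0.24	-0.28	-0.21	-0.24	6.41e-31	IRG	N_Shore
cg02556393	3	168866705	MECOM	-0.08	-0.09	-0.10	-0.09	3.14e-95		N_Shore
cg07809027	4	15007205	CPEB2	-0.07	-0.10	-0.12	-0.10	2.08e-14		S_Shore
cg02215171	4	89379156	HERC5	-0.08	-0.09	-0.11	-0.09	4.48e-18	IRG	S_Shore
cg17786255	4	108814389	SGMS2	-0.07	-0.09	-0.11	-0.09	2.01e-16	IRG
cg21873524	4	190942744		-0.10	-0.10	-0.12	-0.11	1.03e-55		Island
cg24740632	5	134486678		-0.11	-0.12	-0.14	-0.12	2.26e-60
cg06012695	6	28770593			-0.10	-0.13	-0.11	3.59e-16
cg25138053	6	31368016		-0.11	-0.09	-0.07	-0.09	3.67e-15		S_Shore
cg22708150	6	31649619	LY6G5C	-0.12	-0.14	-0.17	-0.14	1.05e-19		N_Shore
cg07292773	6	156718177		0.07	0.10	0.11	0.10	2.22e-17		Island
cg12013713	7	139760671	PARP12	-0.12	-0.14	-0.09	-0.12	1.44e-16	IRG	N_Shore
cg20190772	8	48572496	KIAA0146	-0.08	-0.07	-0.13	-0.09	1.40e-8
cg14864167	8	66751182	PDE7A	-0.25	-0.35	-0.45	-0.35	1.21e-9		N_Shelf
cg06102678	8	81491328		-0.08	-0.12	-0.07	-0.09	1.00e-8		Island
cg12110437	8	144098888	LY6E	-0.16	-0.17	-0.27	-0.20	3.14e-9	IRG	N_Shore
cg17555806	10	74448117		-0.08	-0.12	-0.07	-0.09	1.51e-8		N_Shelf
cg02314339	10	91020653		-0.08	-0.14	-0.11	-0.11	1.72e-8
cg06188083	10	91093005	IFIT3	-0.29	-0.16	-0.31	-0.25	6.18e-8	IRG
cg05552874	10	91153143	IFIT1	-0.20	-0.28	-0.30	-0.26	6.01e-16	IRG
cg14910175	10	131840954		-0.07	-0.11	-0.08	-0.09	1.56e-11		N_Shelf
cg10552523	11	313478	IFITM1	-0.14	-0.12	-0.14	-0.13	5.90e-115	IRG	N_Shelf
cg20566897	11	313527	IFITM1	-0.11	-0.11	-0.09	-0.10	7.00e-62	IRG	N_Shelf
cg23570810	11	315102	IFITM1	-0.24	-0.25	-0.34	-0.27	1.43e-18	IRG	N_Shore
cg03038262	11	315262	IFITM1	-0.24	-0.22	-0.29	-0.25	4.41e-40	IRG	N_Shore
cg20045320	11	319555		-0.19	-0.13	-0.20	-0.18	4.85e-17		S_Shore
cg17990365	11	319718	IFITM3	-0.16	-0.15	-0.15	-0.16	8.78e-295	IRG	S_Shore
cg08926253	11	614761	IRF7	-0.15	-0.14	-0.23	-0.17	2.01e-9	IRG	Island
cg12461141	11	5710654	TRIM22	-0.10	-0.08	-0.12	-0.10	6.35e-25	IRG
cg23571857	17	6658898	XAF1	-0.07	-0.13	-0.11	-0.10	1.46e-8	IRG
cg04927537	17	76976091	LGALS3BP	-0.14	-0.11	-0.20	-0.15	2.77e-10	IRG
cg25178683	17	76976267	LGALS3BP	-0.15	-0.11	-0.21	-0.16	2.01e-8	IRG
cg16503797	18	19476805		-0.08	-0.12	-0.08	-0.09	5.39e-12		N_Shore
cg15871086	18	56526595		-0.07	-0.11	-0.08	-0.09	2.08e-11		N_Shelf
cg23352030	20	62198469	PRIC285	0.13	0.19	0.11	0.14	2.36e-11		Island
cg16785077	21	42791867	MX1	-0.11	-0.09	-0.12	-0.11	8.45e-27	IRG	N_Shore
cg22862003	21	42797588	MX1	-0.31	-0.25	-0.35	-0.31	1.62e-25	IRG	N_Shore
cg26312951	21	42797847	MX1	-0.26	-0.17	-0.20	-0.21	6.28e-15	IRG	N_Shore
cg21549285	21	42799141	MX1	-0.50	-0.35	-0.57	-0.47	6.59e-13	IRG	S_Shore
cg05543864	22	24979755	GGT1	-0.08	-0.08	-0.10	-0.09	1.44e-45
cg20098015	22	50971140	ODF3B	-0.19	-0.22	-0.21	-0.21	9.88e-83	IRG	S_Shore
cg05523603	22	50973101		-0.17	-0.23	-0.27	-0.22	5.51e-14		S_Shelf
cg02247863	22	50983415		-0.07	-0.10	-0.11	-0.09	2.51e-13		N_Shore
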