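probe_id	chrom	pos	gene	mean_delta	meth_p	irg	lfc_expt1_active	lfc_expt2_active	lfc_expt1_inactive	lfc_expt2_inactive
cg16526047	1	949893	ISG15	-0.11	1.28e-4	IRG	3.1	2.77	2.74	2.59
cg05696877	1	79088769	IFI44L	-0.30	6.60e-6	IRG	3.98	3.8	3.64	3.4
cg01079652	1	79118191	IFI44	-0.34	5.34e-4	IRG	3.54	2.53	3.7	2.33
cg17515347	1	159047163	AIM2	-0.09	3.01e-12	IRG	1.39	0.86	1.08	0.49
cg01028142	2	7004578	CMPK2	-0.33	7.98e-8	IRG	2.76	1.5	2.43	1.51
cg10959651	2	7018020	RSAD2	-0.13	3.14e-14	IRG	4.04	3.32	3.76	3.04
cg14126601	2	37384708	EIF2AK2	-0.10	5.55e-16	IRG	1.47	2.02	1.08	1.68
cg15768138	2	219030752	CXCR1	-0.11	7.38e-27		0.43	0.96	0.38	0.66
cg08122652	3	122281939	PARP9-DTX3L	-0.38	1.11e-9	IRG	1.36	1.56	1.07	1.55
cg06981309	3	146260954	PLSCR1	-0.24	6.41e-31	IRG	1.77	1.25	1.38	1.07
cg02694620	3	172109284	FNDC3B	-0.11	3.80e-3		0.57	0.82	0.41	0.52
cg15065340	3	195632915	TNK2	-0.16	4.04e-3		0.22	0.31	0.2	0.25
cg07809027	4	15007205	CPEB2	-0.10	2.08e-14		0.66	0.52	0.42	0.45
cg02215171	4	89379156	HERC5	-0.09	4.48e-18	IRG	2.62	2.48	2.14	2.36
cg05883128	4	169239131	DDX60	-0.25	2.13e-5	IRG	1.24	1.38	1.06	1.46
cg08099136	6	32811251	PSMB8	-0.11	1.43e-4	IRG	-0.39	-0.13	NS	NS
cg00052684	6	35694245	FKBP5	-0.16	1.65e-3		1.11	0.71	NS	NS
cg05994974	7	139761087	PARP12	-0.15	6.89e-5	IRG	1.52	1.57	1.14	1.25
cg14864167	8	66751182	PDE7A	-0.35	1.21e-9		-1.24	-0.41	-0.82	-0.23
cg12110437	8	144098888	LY6E	-0.20	3.14e-9	IRG	2.66	1.92	2.43	1.7
cg03848588	9	32525008	DDX58	-0.10	4.34e-4	IRG	1.48	1.3	1.32	1.07
cg06188083	10	91093005	IFIT3	-0.25	6.18e-8	IRG	2.25	3.15	2.3	2.87
cg05552874	10	91153143	IFIT1	-0.26	6.01e-16	IRG	3.39	2.94	3.42	2.81
cg23570810	11	315102	IFITM1	-0.27	1.43e-18	IRG	1	1.03	1.03	0.81
cg17990365	11	319718	IFITM3	-0.16	8.78e-295	IRG	0.92	2.23	0.71	2.13
cg08926253	11	614761	IRF7	-0.17	2.01e-9	IRG	1.84	1.79	1.4	1.37
cg08577913	11	4415193	TRIM21	-0.10	1.74e-3	IRG	0.56	0.93	0.28	0.75
cg12461141	11	5710654	TRIM22	-0.10	6.35e-25	IRG	1.14	1	0.99	1.05
cg26811705	11	118781408	BCL9L	-0.09	1.64e-3		-0.6	-0.35	-0.41	-0.32
cg19347790	12	81332050	LIN7A	-0.09	1.87e-4		0.93	0.99	1.24	0.61
cg25800166	12	113375896	OAS3	-0.13	5.36e-5	IRG	2.52	2.69	0.73	2.35
cg19371652	12	113415883	OAS2	-0.11	2.24e-5	IRG	1.48	1.56	1.64	1.53
cg03753191	13	43566902	EPSTI1	-0.10	9.23e-5	IRG	2.65	2.26	2.71	2.02
cg00246969	13	99159656	STK24	-0.11	6.26e-6		0.81	0.32	0.66	0.36
cg07839457	16	57023022	NLRC5	-0.23	6.10e-6	IRG	0.7	0.23	0.53	0.27
cg23571857	17	6658898	XAF1	-0.10	1.46e-8	IRG	2.85	1.96	2.35	1.68
cg23378941	17	64361956	PRKCA	-0.11	6.89e-5	IRG	-1.11	-0.3	NS	NS
cg25178683	17	76976267	LGALS3BP	-0.16	2.0e-8	IRG	1.16	1.21	0.72	1.05
cg07573872	19	1126342	SBNO2	-0.15	2.77e-3	IRG	0.38	0.58	NS	NS
cg07839313	19	17514600	BST2	-0.12	3.48e-3	IRG	1.24	0.49	1.17	0.41
cg21549285	21	42799141	MX1	-0.47	6.59e-13	IRG	2.12	2	1.86	1.79
cg19460508	22	44422195	PARVB	-0.10	1.64e-3		0.54	0.39	NS	NS
cg20098015	22	50971140	ODF3B	-0.21	9.88e-83	IRG	1.61	0.61	1.36	0.47
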