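probe_id	chrom	pos	gene	mean_delta	meth_p	irg	lfc_glomerulus	lfc_tubulointerstitium
cg16526047	1	949893	ISG15	-0.11	1.28e-4	IRG	3.32	4.7
cg05696877	1	79088769	IFI44L	-0.30	6.60e-6	IRG	5.14	5.94
cg01079652	1	79118191	IFI44	-0.34	5.34e-4	IRG	3.94	4.76
cg17515347	1	159047163	AIM2	-0.09	3.01e-12	IRG	0.58	NS
cg01028142	2	7004578	CMPK2	-0.33	7.98e-8	IRG	NS	NS
cg10959651	2	7018020	RSAD2	-0.13	3.14e-14	IRG	4.31	3.36
cg14126601	2	37384708	EIF2AK2	-0.10	5.55e-16	IRG	1.54	1.72
cg15768138	2	219030752	CXCR1	-0.11	7.38e-27		0.68	-0.17
cg08122652	3	122281939	PARP9-DTX3L	-0.38	1.11e-9	IRG	NS	NS
cg06981309	3	146260954	PLSCR1	-0.24	6.41e-31	IRG	1.92	2.07
cg02694620	3	172109284	FNDC3B	-0.11	3.80e-3		NS	0.47
cg15065340	3	195632915	TNK2	-0.16	4.04e-3		0.38	-0.4
cg07809027	4	15007205	CPEB2	-0.10	2.08e-14		NS	NS
cg02215171	4	89379156	HERC5	-0.09	4.48e-18	IRG	3.16	1.96
cg05883128	4	169239131	DDX60	-0.25	2.13e-5	IRG	1.11	2.31
cg08099136	6	32811251	PSMB8	-0.11	1.43e-4	IRG	0.76	2.51
cg00052684	6	35694245	FKBP5	-0.16	1.65e-3		-1.27	-2.77
cg05994974	7	139761087	PARP12	-0.15	6.89e-5	IRG	2.26	1.86
cg14864167	8	66751182	PDE7A	-0.35	1.21e-9		NS	NS
cg12110437	8	144098888	LY6E	-0.20	3.14e-9	IRG	1.28	1.23
cg03848588	9	32525008	DDX58	-0.10	4.34e-4	IRG	2.89	2.59
cg06188083	10	91093005	IFIT3	-0.25	6.18e-8	IRG	2.59	3.14
cg05552874	10	91153143	IFIT1	-0.26	6.01e-16	IRG	2.24	2.77
cg23570810	11	315102	IFITM1	-0.27	1.43e-18	IRG	2.24	3.29
cg17990365	11	319718	IFITM3	-0.16	8.78e-295	IRG	2.24	2
cg08926253	11	614761	IRF7	-0.17	2.01e-9	IRG	2.8	1
cg08577913	11	4415193	TRIM21	-0.10	1.74e-3	IRG	1.35	0.77
cg12461141	11	5710654	TRIM22	-0.10	6.35e-25	IRG	1.73	2.86
cg26811705	11	118781408	BCL9L	-0.09	1.64e-3		NS	NS
cg19347790	12	81332050	LIN7A	-0.09	1.87e-4		NS	-0.57
cg25800166	12	113375896	OAS3	-0.13	5.36e-5	IRG	3.77	1.1
cg19371652	12	113415883	OAS2	-0.11	2.24e-5	IRG	4.86	1.74
cg03753191	13	43566902	EPSTI1	-0.10	9.23e-5	IRG	NS	NS
cg00246969	13	99159656	STK24	-0.11	6.26e-6		NS	0.28
cg07839457	16	57023022	NLRC5	-0.23	6.10e-6	IRG	NS	NS
cg23571857	17	6658898	XAF1	-0.10	1.46e-8	IRG	3.14	3.05
cg23378941	17	64361956	PRKCA	-0.11	6.89e-5	IRG	-0.48	-0.08
cg25178683	17	76976267	LGALS3BP	-0.16	2.0e-8	IRG	0.57	1.49
cg07573872	19	1126342	SBNO2	-0.15	2.77e-3	IRG	NS	NS
cg07839313	19	17514600	BST2	-0.12	3.48e-3	IRG	NS	2.91
cg21549285	21	42799141	MX1	-0.47	6.59e-13	IRG	4.05	4.64
cg19460508	22	44422195	PARVB	-0.10	1.64e-3		0.28	NS
cg20098015	22	50971140	ODF3B	-0.21	9.88e-83	IRG	NS	NS
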