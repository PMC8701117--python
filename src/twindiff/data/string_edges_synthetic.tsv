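node_a	node_b	score
ISG15	IFI44L	0.86
ISG15	IFI44	0.834
ISG15	MX1	0.849
ISG15	IFIT1	0.952
ISG15	IFIT3	0.96
ISG15	IFITM1	0.83
ISG15	IFITM3	0.833
ISG15	RSAD2	0.817
ISG15	OAS2	0.887
ISG15	OAS3	0.887
ISG15	IRF7	0.909
IFI44L	IFI44	0.835
IFI44L	MX1	0.97
IFI44L	IFIT1	0.914
IFI44L	IFIT3	0.965
IFI44L	IFITM1	0.849
IFI44L	IFITM3	0.951
IFI44L	RSAD2	0.956
IFI44L	OAS2	0.843
IFI44L	OAS3	0.873
IFI44L	IRF7	0.904
IFI44	MX1	0.949
IFI44	IFIT1	0.922
IFI44	IFIT3	0.835
IFI44	IFITM1	0.801
IFI44	IFITM3	0.842
IFI44	RSAD2	0.816
IFI44	OAS2	0.865
IFI44	OAS3	0.946
IFI44	IRF7	0.854
MX1	IFIT1	0.917
MX1	IFIT3	0.952
MX1	IFITM1	0.912
MX1	IFITM3	0.969
MX1	RSAD2	0.831
MX1	OAS2	0.957
MX1	OAS3	0.952
MX1	IRF7	0.826
IFIT1	IFIT3	0.978
IFIT1	IFITM1	0.864
IFIT1	IFITM3	0.979
IFIT1	RSAD2	0.974
IFIT1	OAS2	0.918
IFIT1	OAS3	0.853
IFIT1	IRF7	0.963
IFIT3	IFITM1	0.804
IFIT3	IFITM3	0.816
IFIT3	RSAD2	0.81
IFIT3	OAS2	0.813
IFIT3	OAS3	0.847
IFIT3	IRF7	0.82
IFITM1	IFITM3	0.821
IFITM1	RSAD2	0.837
IFITM1	OAS2	0.984
IFITM1	OAS3	0.819
IFITM1	IRF7	0.973
IFITM3	RSAD2	0.862
IFITM3	OAS2	0.872
IFITM3	OAS3	0.983
IFITM3	IRF7	0.818
RSAD2	OAS2	0.92
RSAD2	OAS3	0.969
RSAD2	IRF7	0.967
OAS2	OAS3	0.964
OAS2	IRF7	0.863
OAS3	IRF7	0.949
DDX58	DDX60	0.968
DDX58	EIF2AK2	0.988
DDX58	AIM2	0.977
DDX58	TRIM21	0.963
DDX58	TRIM22	0.957
DDX58	PLSCR1	0.959
DDX58	PARP12	0.956
DDX58	CMPK2	0.965
DDX60	EIF2AK2	0.725
DDX60	AIM2	0.831
DDX60	TRIM21	0.833
DDX60	TRIM22	0.753
DDX60	PLSCR1	0.751
DDX60	PARP12	0.81
DDX60	CMPK2	0.839
EIF2AK2	AIM2	0.721
EIF2AK2	TRIM21	0.734
EIF2AK2	TRIM22	0.834
EIF2AK2	PLSCR1	0.758
EIF2AK2	PARP12	0.757
EIF2AK2	CMPK2	0.778
AIM2	TRIM21	0.862
AIM2	TRIM22	0.832
AIM2	PLSCR1	0.755
AIM2	PARP12	0.887
AIM2	CMPK2	0.863
TRIM21	TRIM22	0.789
TRIM21	PLSCR1	0.865
TRIM21	PARP12	0.875
TRIM21	CMPK2	0.887
TRIM22	PLSCR1	0.787
TRIM22	PARP12	0.771
TRIM22	CMPK2	0.827
PLSCR1	PARP12	0.856
PLSCR1	CMPK2	0.874
PARP12	CMPK2	0.759
LY6E	ISG15	0.62
LY6E	IFITM1	0.55
HERC5	ISG15	0.68
HERC5	IFI44	0.52
XAF1	IRF7	0.58
XAF1	MX1	0.51
EPSTI1	ISG15	0.47
BST2	IFITM3	0.57
NLRC5	TRIM21	0.49
PRKCA	DDX58	0.44
LGALS3BP	LY6E	0.35
PSMB8	NLRC5	0.31
CXCR1	PDE7A	0.22
IRF7	DDX58	0.61
ISG15	DDX58	0.52
IFIT1	EIF2AK2	0.46
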