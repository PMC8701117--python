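probe_id	chrom	pos	gene	mean_delta	meth_p	stitch	ipa	dgidb
cg16526047	1	949893	ISG15	-0.11	1.28e-4			Irinotecan^F^
cg10959651	2	7018020	RSAD2	-0.13	3.14e-14	Fludarabine^F^
cg14126601	2	37384708	EIF2AK2	-0.10	5.55e-16			Indirubin derivative E804
cg15768138	2	219030752	CXCR1	-0.11	7.38e-27	Reparixin^D^	Reparixin^D^	SCH-527123, Ketoprofen^F^
cg06981309	3	146260954	PLSCR1	-0.24	6.41e-31	Wogonin^G^
cg15065340	3	195632915	TNK2	-0.16	4.04e-3	Dasatinib^-1 F^	Osimertinib^F^, Vemurafenib^F^	Debromohymenialdisine
cg08099136	6	32811251	PSMB8	-0.11	1.43e-4	Carfilzomib^4 F^, Oprozomib^D^, Bortezomib^6 F^	Carfilzomib^4 F^	Carfilzomib^4 F^
cg00052684	6	35694245	FKBP5	-0.16	1.65e-3	Rapamycin/Sirolimus^2 F^, Tacrolimus^5 F^		Venlafaxine^F^, Clomipramine^F^
cg14864167	8	66751182	PDE7A	-0.35	1.21e-9			Ketotifen^F^, Dyphylline^F^
cg12110437	8	144098888	LY6E	-0.20	3.14e-9		DLYE5953A^D^
cg06188083	10	91093005	IFIT3	-0.25	6.18e-8	Imidazoles^D^
cg08926253	11	614761	IRF7	-0.17	2.01e-9	Hesperidin^D^
cg03753191	13	43566902	EPSTI1	-0.10	9.23e-5	Methotrexate^F T^, Vinblastine^F^, Doxorubicin^F^, Cisplatin^F^
cg00246969	13	99159656	STK24	-0.11	6.26e-6	Staurosporine^D^
cg23378941	17	64361956	PRKCA	-0.11	6.89e-5	Staurosporine^D^	Aprinocarsen	Midostaurin^F^, Enzastaurin^D^, Quercetin^D G^, Aprinocarsen, Ruboxistaurin^D^, Ingenol Mebutate^FW^, Bryostatin^D^, Sotrastaurin Acetate^D^, Tamoxifen^2 F^
cg07839313	19	17514600	BST2	-0.12	3.48e-3	Resveratrol^6 D G^
cg21549285	21	42799141	MX1	-0.47	6.59e-13	Mitomycin C^F^, Colchicine^F^
cg19460508	22	44422195	PARVB	-0.10	1.64e-3	Lovastatin^3 F^		Bortezomib^6 F^
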