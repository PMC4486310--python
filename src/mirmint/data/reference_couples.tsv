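mir	gene	r_day0	r_day7	r_day14
hsa-miR-1305	ID1			-0.886
hsa-miR-202	CBFA2T3			0.931
hsa-miR-34a	AKT3		-0.909
hsa-miR-34a	ARHGAP29		-0.927
hsa-miR-34a	C18orf25	-0.945	-0.917
hsa-miR-34a	C1orf74	0.827	0.827
hsa-miR-34a	CD40	0.945
hsa-miR-34a	DOK6	-0.885	-0.885
hsa-miR-34a	DTNA	-0.892
hsa-miR-34a	GALM		0.815
hsa-miR-34a	GRB10		-0.842
hsa-miR-34a	KCTD12		-0.87
hsa-miR-34a	KCTD21		0.813
hsa-miR-34a	LMAN1	-0.884	-0.88
hsa-miR-34a	MEX3C	-0.938	-0.938
hsa-miR-34a	NTNG1	-0.856	-0.856
hsa-miR-34a	NTNG1		-0.856
hsa-miR-34a	PEG10		-0.941
hsa-miR-34a	RPRD1A		-0.877
hsa-miR-34a	SMAD4	-0.904	-0.904
hsa-miR-34a	SOCS6	-0.982	-0.994
hsa-miR-34a	TMEM164		0.88
hsa-miR-34a	TNFRSF9		0.882
hsa-miR-34a	TXNL1		-0.931
hsa-miR-34a	ZFYVE21		-0.878
hsa-miR-34a	ZNF3		0.823
hsa-miR-378	KIF26A	0.848
hsa-miR-500	NEBL			-0.903
hsa-miR-520e	C18orf25			-0.823
hsa-miR-520e	EFNB2			-0.813
hsa-miR-892b	BACH2		0.813
hsa-miR-26b	ADAMTSL1			-0.929
hsa-miR-26b	ADNP2			0.94
hsa-miR-26b	ARHGAP29			0.924
hsa-miR-26b	C18orf25			0.918
hsa-miR-26b	CDH2			0.968
hsa-miR-26b	CNR1			0.844
hsa-miR-26b	DTNA			0.908
hsa-miR-26b	ELAVL2			0.885
hsa-miR-26b	HES1			0.909
hsa-miR-26b	HEY2			0.94
hsa-miR-26b	JAM2			0.9
hsa-miR-26b	KIAA1468			0.917
hsa-miR-26b	MEX3C			0.99
hsa-miR-26b	NEDD4L			0.883
hsa-miR-26b	NTNG1			0.907
hsa-miR-26b	PLEKHA7			0.863
hsa-miR-26b	RNF138			0.829
hsa-miR-26b	SMAD2			0.816
hsa-miR-26b	SMAD4			0.933
hsa-miR-26b	STX6			-0.858
hsa-miR-26b	TECPR2			0.885
hsa-miR-26b	VPS4B			0.864
hsa-miR-342-3p	BARD1			0.835
hsa-miR-342-3p	C18orf25			0.934
hsa-miR-342-3p	EFNB2			0.866
hsa-miR-342-3p	IGFBP5			0.897
hsa-miR-342-3p	KCTD12			0.923
hsa-miR-342-3p	KIAA1468			0.834
hsa-miR-342-3p	KIFAP3			-0.903
hsa-miR-342-3p	LPPR4			0.872
hsa-miR-342-3p	MEGF6			0.951
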