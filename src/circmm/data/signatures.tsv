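signature_name	gene_id
bergsagel	TYMS
bergsagel	TK1
bergsagel	CCNB1
bergsagel	MKI67
bergsagel	TOP2A
bergsagel	BIRC5
bergsagel	CCNB2
bergsagel	CDC20
bergsagel	AURKB
bergsagel	PLK1
bergsagel	BUB1
bergsagel	KIF20A
shaughnessy	RRM2
shaughnessy	PCNA
shaughnessy	MCM2
shaughnessy	CDK1
shaughnessy	CENPA
shaughnessy	KIF11
shaughnessy	ASPM
shaughnessy	NUSAP1
shaughnessy	UBE2C
shaughnessy	TPX2
shaughnessy	FOXM1
hose	CCNA2
hose	CDC6
hose	CDC45
hose	CDT1
hose	CHEK1
hose	E2F1
hose	ESPL1
hose	EXO1
hose	FEN1
hose	GINS1
hose	GINS2
hose	HELLS
hose	PCLAF
hose	KIF15
hose	KIF23
hose	KIF2C
hose	LIG1
hose	MAD2L1
hose	MCM3
hose	MCM4
hose	MCM5
hose	MCM6
hose	MCM7
hose	MELK
hose	MYBL2
hose	NDC80
hose	NCAPG
hose	ORC1
hose	ORC6
hose	POLA1
hose	POLE2
hose	PRC1
hose	RAD51
hose	RFC3
hose	RFC4
hose	RNASEH2A
hose	RRM1
hose	SHCBP1
hose	SPAG5
hose	SPC25
hose	TCF19
hose	TIMELESS
hose	TRIP13
hose	TTK
hose	AURKA
hose	CENPE
hose	CENPF
hose	DLGAP5
hose	HMMR
hose	CKAP2
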