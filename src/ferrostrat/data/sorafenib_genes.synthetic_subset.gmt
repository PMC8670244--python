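SORAFENIB_POSITIVE	drug_positive	FLT3
SORAFENIB_NEGATIVE	drug_negative	MAPK1	MAPK3	GADD45G	MCL1	PINK1
SORAFENIB_ASSOCIATED	signature	FLT3	MAPK1	MAPK3	GADD45G	MCL1	PINK1	KIT	RAF1	BRAF	VEGFA	PDGFRB	KDR	RET	CCND1	CDK4	MAP2K1	MAP2K2	EGFR	ERBB2	MYC	JUN	FOS	STAT3	AKT1	MTOR	BCL2	BAX	CASP3	TNF	IL6
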