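FE_DRIVER	driver	NRAS	KRAS	FLT3	CDKN2A	ACSL4	ALOX15	LPCAT3	SAT1	TFRC	CARS	ATP5G3	GLS2	NCOA4	EGFR	IDH1	PIK3CA	HRAS	KEAP1	ATG5	ATG7	PANX1
FE_SUPPRESSOR	suppressor	TP53	GPX4	SLC7A11	FDFT1	HSPA5	HSPB1	NFE2L2	CISD1	CD44	FTH1	FTL	MUC1	NQO1	PROM2	SCD
FE_MARKER	marker	CDKN1A	SLC1A5	RPL8	EMC2	CS	FANCD2	DPP4	MT1G	PTGS2	CHAC1	SLC38A1	AKR1C1	AKR1C2	AKR1C3	GCLC
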