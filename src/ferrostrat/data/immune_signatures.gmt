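CYTOLYTIC	signature	GZMA	GZMB	GZMH	GZMK	GZMM	PRF1
INFLAMMATORY	signature	IL1B	IL6	IL8	TNF	IFNG	CCL2	CCL5	CXCL9	CXCL10	PTGS2	NOS2	STAT1
IFNG_6	signature	IFNG	STAT1	IDO1	CXCL10	CXCL9	HLA-DRA
EXPANDED_IMMUNE_18	signature	CD3D	IDO1	CIITA	CD3E	CCL5	GZMK	CD2	HLA-DRA	CXCL13	IL2RB	NKG7	HLA-E	CXCR6	LAG3	TAGAP	CXCL10	STAT1	GZMB
HLA_CLASS_I	signature	HLA-A	HLA-B	HLA-C
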