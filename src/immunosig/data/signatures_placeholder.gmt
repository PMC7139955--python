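TCT	T-cell trafficking: CXCR3 ligands	CXCL9	CXCL10	CXCL11
CLIS	Cytotoxic Lymphocyte Immune Signature (57-gene placeholder membership; edit to taste)	CD8A	CD8B	CD2	CD3D	CD3E	CD3G	CD247	LCK	ZAP70	ITK	LAT	SKAP1	THEMIS	PTPRC	CD28	ICOS	CD27	TNFRSF9	TNFRSF18	CTLA4	PDCD1	LAG3	TIGIT	CD96	CRTAM	SLAMF6	SH2D1A	GZMA	GZMB	GZMH	GZMK	GZMM	PRF1	GNLY	NKG7	CTSW	FASLG	KLRB1	KLRC1	KLRD1	KLRK1	NCR1	EOMES	TBX21	RUNX3	STAT4	IFNG	IL2RB	IL2RG	IL7R	CCL4	CCL5	XCL1	XCL2	CCR5	CXCR6	CST7
M2TAM	M2 tumor-associated macrophage signature (4-gene placeholder membership; edit to taste)	CD163	MRC1	MSR1	CCL22
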