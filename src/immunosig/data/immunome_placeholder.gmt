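B.cells.naive	immunome class (placeholder membership; edit to taste)	MS4A1	CD19	CR2	TCL1A
B.cells.memory	immunome class (placeholder membership; edit to taste)	CD27	CD79A	CD79B
Plasma.cells	immunome class (placeholder membership; edit to taste)	IGHG1	MZB1	SDC1	XBP1
T.cells.CD8	immunome class (placeholder membership; edit to taste)	CD8A	CD8B	GZMA	GZMB	GZMH	GZMK	GZMM	PRF1	NKG7	CTSW	FASLG	CST7	LAG3	CD96	CRTAM	EOMES	IL2RB	CCL4	CCL5	CXCR6
T.cells.CD4.naive	immunome class (placeholder membership; edit to taste)	CCR7	SELL	IL7R	TCF7
T.cells.CD4.memory.resting	immunome class (placeholder membership; edit to taste)	CD28	CD3D	CD3E	CD3G	CD247	LCK	ZAP70	ITK	LAT	SKAP1	THEMIS	PTPRC	CD2
T.cells.CD4.memory.activated	immunome class (placeholder membership; edit to taste)	ICOS	CD27	TNFRSF9	TNFRSF18	IL2RG	STAT4
T.cells.follicular.helper	immunome class (placeholder membership; edit to taste)	CXCR5	BCL6	SH2D1A	SLAMF6
T.cells.regulatory	immunome class (placeholder membership; edit to taste)	FOXP3	CTLA4	IL2RA	TIGIT	PDCD1
T.cells.gamma.delta	immunome class (placeholder membership; edit to taste)	TRGC1	TRDC	KLRB1
NK.cells.resting	immunome class (placeholder membership; edit to taste)	KLRC1	KLRD1	KLRK1	NCR1	XCL1	XCL2
NK.cells.activated	immunome class (placeholder membership; edit to taste)	GNLY	IFNG	TBX21	RUNX3	CCR5
Monocytes	immunome class (placeholder membership; edit to taste)	CD14	LYZ	FCN1	S100A8
Macrophages.M0	immunome class (placeholder membership; edit to taste)	CD68	MARCO	ACP5
Macrophages.M1	immunome class (placeholder membership; edit to taste)	CXCL9	CXCL10	CXCL11	IDO1	IL1B	SOCS1
Macrophages.M2	immunome class (placeholder membership; edit to taste)	CD163	MRC1	MSR1	CCL22	IL10	CCL13
Dendritic.cells.resting	immunome class (placeholder membership; edit to taste)	CD1C	FCER1A	CLEC10A
Dendritic.cells.activated	immunome class (placeholder membership; edit to taste)	CCR7	LAMP3	CCL19
Mast.cells.resting	immunome class (placeholder membership; edit to taste)	TPSAB1	CPA3	MS4A2
Mast.cells.activated	immunome class (placeholder membership; edit to taste)	KIT	CMA1
Eosinophils	immunome class (placeholder membership; edit to taste)	CLC	PRG2	IL5RA
Neutrophils	immunome class (placeholder membership; edit to taste)	FCGR3B	CSF3R	S100A12	CEACAM8
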