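# literature-based cell-lineage markers (cell_type <tab> gene)
EC	PLVAP
EC	KDR
EC	PTPRB
enteroendocrine	CHGA
enteroendocrine	GAST
enteroendocrine	PROX1
fibroblast	MMP2
fibroblast	PDGFRA
fibroblast	MYL9
fibroblast	FN1
fibroblast	CAV1
GMC	MUC6
GMC	TFF2
IM	TFF3
IM	CDX1
IM	CDX2
chief	PGC
goblet	MUC2
goblet	ITLN1
goblet	HES6
MSC	OLFM4
MSC	REG1A
MSC	CLDN3
PC	CDKN2A
PC	MKI67
PC	RBP4
PMC	GKN1
PMC	GKN2
PMC	MUC5AC
tumor	EPCAM
tumor	CDH17
tumor	COL3A1
tumor	PDGFRB
immune	PTPRC
immune	CD3D
immune	CD79A
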