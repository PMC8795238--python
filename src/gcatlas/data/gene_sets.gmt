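EMT	synthetic default	VIM	SNAI1	SNAI2	ZEB1	ZEB2	TWIST1	CDH2	FN1	S100A4	COL1A1	COL1A2	SPARC
EmyoT	synthetic default	TAGLN	EGR1	MRTFA	SRF	IGFBP5	ACTA2	CNN1	LMOD1
stemness	synthetic default	NANOG	POU5F1	SOX2	MYC	PROM1	ALDH1A1	LGR5	OLFM4
intestinal	synthetic default	CDH17	MUC13	REG4	CEACAM5	KRT8	TFF3	CDX1	CDX2
G1S	synthetic default	CCND1	CCNE1	CDK4	CDK6	E2F1	MCM2	PCNA	CDC6
iCAF	synthetic default	IL6	IL11	IL24	CXCL1	CXCL2	CXCL5	CXCL6	MMP1	MMP3	MMP10
myCAF	synthetic default	TPM1	TPM2	MYL9	TAGLN	POSTN	ACTA2
inCAF	synthetic default	PDGFRA	ID1	ID3	POSTN
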