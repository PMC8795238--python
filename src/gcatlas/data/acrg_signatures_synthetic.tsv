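gene	MSS_TP53_pos	MSS_TP53_neg	MSI	EMT	EmyoT
CDH17	5.0	0.5	0.5	0.5	0.5
MUC13	5.0	0.5	0.5	0.5	0.5
REG4	5.0	0.5	0.5	0.5	0.5
MDM2	5.0	0.5	0.5	0.5	0.5
CDKN1A	5.0	0.5	0.5	0.5	0.5
CEACAM5	0.5	5.0	0.5	0.5	0.5
KRT8	0.5	5.0	0.5	0.5	0.5
TFF3	0.5	5.0	0.5	0.5	0.5
CCNE1	0.5	5.0	0.5	0.5	0.5
MYC	0.5	5.0	0.5	0.5	0.5
MLH1	0.5	0.5	5.0	0.5	0.5
MSH2	0.5	0.5	5.0	0.5	0.5
MSH6	0.5	0.5	5.0	0.5	0.5
VIM	0.5	0.5	0.5	5.0	0.5
ZEB1	0.5	0.5	0.5	5.0	0.5
SNAI2	0.5	0.5	0.5	5.0	0.5
CDH2	0.5	0.5	0.5	5.0	0.5
FN1	0.5	0.5	0.5	5.0	0.5
SPARC	0.5	0.5	0.5	5.0	0.5
COL1A2	0.5	0.5	0.5	5.0	0.5
TAGLN	0.5	0.5	0.5	0.5	5.0
EGR1	0.5	0.5	0.5	0.5	5.0
MRTFA	0.5	0.5	0.5	0.5	5.0
SRF	0.5	0.5	0.5	0.5	5.0
IGFBP5	0.5	0.5	0.5	0.5	5.0
ACTA2	0.5	0.5	0.5	0.5	5.0
IL6	0.5	0.5	0.5	0.5	1.5
IL11	0.5	0.5	0.5	0.5	1.5
IL24	0.5	0.5	0.5	0.5	1.5
CXCL1	0.5	0.5	0.5	0.5	1.5
CXCL2	0.5	0.5	0.5	0.5	1.5
CXCL5	0.5	0.5	0.5	0.5	1.5
CXCL6	0.5	0.5	0.5	0.5	1.5
MMP1	0.5	0.5	0.5	0.5	1.5
MMP3	0.5	0.5	0.5	0.5	1.5
MMP10	0.5	0.5	0.5	0.5	1.5
NANOG	0.5	0.5	0.5	0.5	1.5
POU5F1	0.5	0.5	0.5	0.5	1.5
SOX2	0.5	0.5	0.5	0.5	1.5
PROM1	0.5	0.5	0.5	0.5	1.5
ALDH1A1	0.5	0.5	0.5	0.5	1.5
LGR5	0.5	0.5	0.5	0.5	1.5
OLFM4	0.5	0.5	0.5	0.5	1.5
TPM1	0.5	0.5	0.5	0.5	2.0
TPM2	0.5	0.5	0.5	0.5	2.0
MYL9	0.5	0.5	0.5	0.5	2.0
POSTN	0.5	0.5	0.5	0.5	2.0
PDGFRA	0.5	0.5	0.5	0.8	1.0
ID1	0.5	0.5	0.5	0.8	1.0
ID3	0.5	0.5	0.5	0.8	1.0
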