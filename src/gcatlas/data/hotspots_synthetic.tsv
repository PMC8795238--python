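variant_id	gene	position	protein_change	pathway
CCND1_T286	CCND1	69466090	T286	cell_cycle
CCND1_P287	CCND1	69466093	P287	cell_cycle
CDK4_R24	CDK4	58145430	R24	cell_cycle
CDKN2A_R80	CDKN2A	21971120	R80	cell_cycle
RB1_R455	RB1	48941648	R455	cell_cycle
KRAS_G12	KRAS	25398284	G12	MAPK
BRAF_V600	BRAF	140453136	V600	MAPK
RAC1_P29	RAC1	6426924	P29	MAPK
PIK3CA_E545	PIK3CA	178936091	E545	PI3K
ERBB2_S310	ERBB2	37868208	S310	RTK
TP53_R175	TP53	7578406	R175	TP53
CTNNB1_S45	CTNNB1	41266137	S45	WNT
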