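CELL_CYCLE	curated seed; edit to taste	CCND1	CCND2	CCND3	CCNE1	CDK2	CDK4	CDK6	CDKN1A	CDKN1B	CDKN2A	CDKN2B	CDKN2C	E2F1	E2F3	RB1
HIPPO	curated seed; edit to taste	CRB1	CRB2	DCHS1	DCHS2	FAT1	FAT2	FAT3	FAT4	LATS1	LATS2	MOB1A	MOB1B	NF2	SAV1	STK3	STK4	TAOK1	TAOK2	TAOK3	TEAD1	TEAD2	WWC1	YAP1
MYC	curated seed; edit to taste	MAX	MGA	MLX	MNT	MXD1	MXD3	MXD4	MXI1	MYC	MYCL	MYCN
NOTCH	curated seed; edit to taste	CNTN6	CREBBP	DLL1	DLL3	DLL4	EP300	FBXW7	HES1	HEY1	JAG1	JAG2	KAT2B	KDM5A	MAML1	MAML2	MAML3	NCOR1	NCOR2	NOTCH1	NOTCH2	NOTCH3	NOTCH4	PSEN2	SPEN
NRF2	curated seed; edit to taste	CUL3	KEAP1	NFE2L2
PI3K	curated seed; edit to taste	AKT1	AKT2	AKT3	DEPDC5	DEPTOR	INPP4B	MTOR	PDK1	PIK3CA	PIK3CB	PIK3R1	PIK3R2	PIK3R3	PPP2R1A	PTEN	RHEB	RICTOR	RPTOR	STK11	TSC1	TSC2
RTK_RAS	curated seed; edit to taste	ABL1	ALK	ARAF	BRAF	CBL	EGFR	ERBB2	ERBB3	ERBB4	ERRFI1	FGFR1	FGFR2	FGFR3	FGFR4	FLT3	HRAS	IGF1R	JAK2	KIT	KRAS	MAP2K1	MAP2K2	MAPK1	MET	NF1	NRAS	NTRK1	NTRK2	NTRK3	PDGFRA	PDGFRB	PTPN11	RAC1	RAF1	RASA1	RET	RIT1	ROS1	SOS1	SPRED1
TGF_BETA	curated seed; edit to taste	ACVR1B	ACVR2A	SMAD2	SMAD3	SMAD4	TGFBR1	TGFBR2
TP53	curated seed; edit to taste	ATM	CHEK2	MDM2	MDM4	RPS6KA3	TP53	TP53BP1
WNT	curated seed; edit to taste	AMER1	APC	AXIN1	AXIN2	CTNNB1	DKK1	DKK2	DKK3	DKK4	GSK3B	LRP5	LRP6	RNF43	SFRP1	SFRP2	SFRP4	SFRP5	TCF7	TCF7L1	TCF7L2	TLE1	TLE2	TLE3	TLE4	WIF1	ZNRF3
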