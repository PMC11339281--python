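intrinsic_apoptosis	synthetic illustrative set (supply a curated GMT for real studies)	BAX	BAK1	BCL2	BCL2L1	MCL1	BID	BBC3	PMAIP1	CYCS	APAF1	CASP9	CASP3	CASP7	TP53	DIABLO
extrinsic_apoptosis	synthetic illustrative set (supply a curated GMT for real studies)	FAS	FASLG	TNFRSF10A	TNFRSF10B	TNFSF10	FADD	CASP8	CASP10	CFLAR	TNFRSF1A	TNF	TRADD	RIPK1	BIRC2	BIRC3
mpt_driven_necrosis	synthetic illustrative set (supply a curated GMT for real studies)	PPIF	VDAC1	VDAC2	VDAC3	SLC25A4	SLC25A5	BAX	ATP5F1A	ATP5F1B	CKMT1A	MPC1	TSPO	HK1	HK2	BNIP3
necroptosis	synthetic illustrative set (supply a curated GMT for real studies)	RIPK1	RIPK3	MLKL	ZBP1	TICAM1	TNF	TNFRSF1A	TRADD	CYLD	SPATA2	PELI1	PGAM5	DNM1L	FADD	CASP8
ferroptosis	synthetic illustrative set (supply a curated GMT for real studies)	GPX4	SLC7A11	SLC3A2	ACSL4	LPCAT3	ALOX15	NCOA4	FTH1	FTL	TFRC	SAT1	NFE2L2	HMOX1	PTGS2	CHAC1
pyroptosis	synthetic illustrative set (supply a curated GMT for real studies)	GSDMD	GSDME	CASP1	CASP4	CASP5	NLRP3	NLRC4	AIM2	PYCARD	IL1B	IL18	NINJ1	CASP11	NLRP1	IL1A
parthanatos	synthetic illustrative set (supply a curated GMT for real studies)	PARP1	AIFM1	MIF	PAR	OGG1	XRCC1	LIG3	POLB	PARG	ADPRHL2	NMNAT1	SIRT6	TDP1	APEX1	FEN1
entotic_cell_death	synthetic illustrative set (supply a curated GMT for real studies)	RHOA	ROCK1	ROCK2	CDH1	CTNNB1	CTNNA1	MYH9	MYL9	LAMP1	RAB5A	RAB7A	UVRAG	PIK3C3	BECN1	ATG5
netotic_cell_death	synthetic illustrative set (supply a curated GMT for real studies)	PADI4	ELANE	MPO	CTSG	PRTN3	DEFA1	CAMP	LTF	MMP8	MMP9	S100A8	S100A9	AZU1	BPI	CYBB
lysosome_dependent_cell_death	synthetic illustrative set (supply a curated GMT for real studies)	CTSB	CTSD	CTSL	LAMP1	LAMP2	TFEB	GLA	HEXB	GBA	MCOLN1	TPP1	GRN	NPC1	SCARB2	PSAP
autophagy_dependent_cell_death	synthetic illustrative set (supply a curated GMT for real studies)	ATG5	ATG7	ATG12	ATG16L1	BECN1	MAP1LC3A	MAP1LC3B	ULK1	ULK2	ATG13	ATG101	WIPI2	SQSTM1	GABARAP	ATG3
immunogenic_cell_death	synthetic illustrative set (supply a curated GMT for real studies)	CALR	HMGB1	ATP1A1	ANXA1	HSPA1A	HSPA1B	HSP90AA1	TLR4	AGER	P2RX7	P2RY2	IFNB1	CXCL10	EIF2AK3	PDIA3
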