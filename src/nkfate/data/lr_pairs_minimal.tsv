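# minimal illustrative ligand-receptor table covering the pathways reported
# for trauma NK communication; supply a full curated database for real studies
ligand	receptor	pathway
CXCL8	CXCR1	CXCL
CXCL8	CXCR2	CXCL
CXCL2	CXCR2	CXCL
ICAM1	ITGB2;ITGAL	ITGB2
ICAM2	ITGB2;ITGAL	ITGB2
PECAM1	PECAM1	PECAM1
JAG1	NOTCH1	NOTCH
JAG2	NOTCH2	NOTCH
DLL1	NOTCH1	NOTCH
ALCAM	CD6	ALCAM
CD8A	LCK	LCK
F2	F2R	PARS
F2	F2RL1	PARS
SCG2	ADGRL1	SN
SELPLG	SELP	SELPLG
SELPLG	SELL	SELPLG
TGFB1	TGFBR1;TGFBR2	TGFB
TGFB2	TGFBR1;TGFBR2	TGFB
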