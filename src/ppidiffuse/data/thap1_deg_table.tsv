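gene	direction	significance	source
AARS2	UP	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
AGPAT1	UP	***	cortical neuronal precursors derived from human iPSC; in vitro
ANLN	DOWN	**	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
ATF4	DOWN	***	THAP1+/-(dExon2) knockout mice; Flp-In T-REx 293 cells; striatum; in vitro
ATP5F1E	UP	***	cortical neuronal precursors derived from human iPSC; in vitro
BDKRB2	DOWN	***	cortical neuronal precursors derived from human iPSC; in vitro
CLN3	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
CNP	DOWN	**	THAP1 Nestin conditional knockout mice; striatum
CRADD	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
CUEDC2	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
CYB5D2	UP	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
DNLZ	UP	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
DPAGT1	DOWN	***	THAP1 Nestin conditional knockout mice; striatum
DPH6	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
DRD2	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
DRD4	UP	***	cortical neuronal precursors derived from human iPSC; in vitro
ECH1	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
EHD3	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
EIF3K	DOWN	**	THAP1+/-(dExon2) knockout mice; cerebellar tissue
EIF4G3	UP	***	cortical neuronal precursors derived from human iPSC; in vitro
ElF2a	DOWN	**	THAP1+/-(dExon2) knockout mice; in vitro; cerebellar tissue
FAM117A	UP	*	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
FAM122B	UP	*	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
HLA-A	DOWN	***	cortical neuronal precursors derived from human iPSC; in vitro
LPAR1	DOWN	*	oligodendrocytes of THAP1 Nestin conditional knockout; THAP1 C54Y/+ mice; in vitro; striatum
LYRM1	UP	**	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
MAG	DOWN	**	oligodendrocytes of THAP1 Nestin conditional knockout; THAP1 C54Y/+ mice; in vitro; striatum
MOBP	DOWN	***	oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
MOG	DOWN	***	oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
PLLP	UP	**	oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
PLP1	DOWN	**	oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
PPP2R3C	UP	**	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
RACGAP1	UP	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
RRM1	DOWN	*	primary striatal neurons; endothelial cells; HUVECs; in vitro
RRM1	UP	**	THAP1 C54Y/+ mice; striatum
SHLD1	DOWN	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
SIGLEC1	DOWN	***	cortical neuronal precursors derived from human iPSC; in vitro
SIX2	DOWN	***	cortical neuronal precursors derived from human iPSC; in vitro
SLC6A13	UP	*	THAP1 C54Y/+ mice; cerebellar tissue
SLX4IP	UP	**	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
SNRNP35	UP	***	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
SOD2	DOWN	*	HEK-293 and SK-N-AS cells; in vitro
STXBP1	DOWN	**	HEK-293 and SK-N-AS cells; in vitro
THAP1	DOWN	**, ***	cortical neuronal precursors derived from human iPSC; human fibroblasts; THAP1 Nestin conditional knockout mice; endothelial cells; cerebellar and striatal tissue
TOMM40	UP	**	THAP1 Nestin conditional knockout mice; cerebellar tissue
TOMM40	DOWN	***	THAP1 Nestin conditional knockout mice; striatum
TOR1A	UP	N/A	SH-SY5Y cells; human fibroblasts; HEK-293T, HUVECs and T98G cells; in vitro
TSPAN2	DOWN	***	oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
UGT8A	DOWN	***	oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
YY1	UP	***	cortical neuronal precursors derived from human iPSC; oligodendrocytes of THAP1 Nestin conditional knockout; in vitro
ZFP882	DOWN	**	THAP1 Nestin conditional knockout mice; cerebellar and striatal tissue
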