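gene	highly_expressed_biopsy
ACHE	0
ACKR3	0
ACOX1	0
ADRA2B	0
ADRA2C	0
ALAS1	0
APP	1
ARHGDIB	0
BMP5	0
C10orf10	0
CCL20	0
CCL21	0
CCL25	0
CCL27	0
CCL28	0
CDC16	1
CDK19	0
CDKN1B	1
CHD7	0
CHD9	0
CITED2	1
CNR2	0
CXCL9	0
DMTF1	1
ERBB2	0
F2	0
FCER1A	0
FCER1G	0
FKBP1A	1
FN1	1
FPR1	0
FPR2	0
FPR3	0
GAB1	0
GAB2	0
GALR1	0
GALR2	0
GALR3	0
GLIPR1	1
GNAI1	0
GNAI3	0
GNG2	0
GTF2F1	0
HNF4A	0
HNF4G	0
HRH3	0
HRH4	0
HSF2	0
HYLS1	0
IGFBP1	0
IGFBP7	1
IL12RB1	0
IL2RA	0
IL2RB	0
IL4R	0
IL6R	0
IL6ST	1
IRF2	0
IRF3	0
IRF5	0
IRF6	0
IRF7	0
ITGAV	1
KRT17	0
KRT5	0
LPAR2	0
ME1	0
MED13L	1
MGP	1
MTNR1A	0
MTNR1B	0
NKX2-5	0
NPY2R	0
NR1D2	0
NR3C1	1
NR5A1	0
P2RY4	0
PELP1	0
PLAUR	0
PRKAG1	0
PRKAG2	0
PTPN11	0
PTPRA	0
RORA	0
RORB	0
RORC	0
SMAD7	0
SMAD9	0
SMARCE1	0
SMURF1	0
SORBS1	0
SOSTDC1	0
SP3	0
SRA1	0
STC1	0
SYT5	0
TAS2R1	0
TAS2R16	0
TAS2R3	0
TAS2R39	0
TAS2R4	0
TAS2R5	0
TGS1	0
TOMM20	1
TRIP6	0
UBE2D1	0
UTRN	0
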