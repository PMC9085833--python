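# Genes with published evidence of a brown-adipose-tissue role,
# including the core gene UCP1. One HGNC symbol per line.
ACSS1
ADRA2A
AKT1
APLNR
BMP2
BMP7
CAV1
CIDEA
CNR1
CPE
CRK
EBF1
EHMT1
FNDC5
FST
FTO
G0S2
GATA2
GHRL
GJA1
IGF1R
IL2RG
IL6
INS
INSR
IRF1
IRF4
IRS1
JUN
LEP
LIF
LRPPRC
MTOR
NGF
NMS
NMU
NPY
NR1D1
NRF1
NRIP1
NTRK1
POMC
PPARA
PPARG
PPARGC1A
PRKAA1
PRKAA2
PTGS2
PYY
RETN
SESN2
SHC1
SIRT3
SMAD1
SMAD4
SP1
TNFRSF1A
UCP1
UCP2
UCP3
YY1
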