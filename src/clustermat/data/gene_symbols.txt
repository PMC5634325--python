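A2M
ABL1
ACTA2
ACTB
ACTG1
AKT1
AKT2
AKT3
ALB
ALK
APC
APOE
AR
ARAF
ATM
ATR
AXIN1
B2M
BAD
BAX
BCL2
BCL2L1
BCR
BRAF
BRCA1
BRCA2
BTK
CALM1
CASP3
CASP8
CASP9
CAV1
CCND1
CCNE1
CD14
CD19
CD36
CD38
CD4
CD40
CD44
CD8A
CDH1
CDK1
CDK2
CDK4
CDK6
CDKN1A
CDKN1B
CDKN2A
CEBPA
CHEK1
CHEK2
CREB1
CRP
CSF1R
CTNNB1
CXCL8
CXCR4
DDIT3
DICER1
DNMT1
DNMT3A
E2F1
EGF
EGFR
EP300
ERBB2
ERBB3
ERBB4
ESR1
EZH2
FAS
FGF2
FGFR1
FGFR2
FGFR3
FLT3
FN1
FOS
FOXO1
FOXO3
GAPDH
GATA1
GATA3
GSK3B
HDAC1
HDAC2
HGF
HIF1A
HLA-A
HLA-B
HLA-DRA
HMGB1
HRAS
HSPA4
HSPB1
IDH1
IDH2
IFNG
IGF1
IGF1R
IL10
IL1B
IL2
IL6
ITGB1
JAK1
JAK2
JUN
KDR
KIT
KRAS
KRT14
KRT18
KRT19
KRT5
KRT8
LDHA
LMNA
MAP2K1
MAP2K2
MAP2K4
MAPK1
MAPK14
MAPK3
MAPK8
MAPKAPK2
MCL1
MDM2
MET
MKI67
MLH1
MMP2
MMP9
MSH2
MTOR
MYC
MYCN
MYD88
NF1
NF2
NFKB1
NKX2-1
NOTCH1
NOTCH2
NPM1
NRAS
NTRK1
PARP1
PCNA
PDGFRA
PDGFRB
PDPK1
PIK3CA
PIK3CB
PIK3R1
PLK1
PML
PPARG
PRKACA
PRKCA
PTEN
PTGS2
PTK2
PTPN11
RAF1
RB1
RELA
RET
RHOA
ROS1
RPS6
RPS6KB1
SFTA3
SFTPC
SMAD2
SMAD3
SMAD4
SMARCA4
SOX2
SOX9
SRC
STAT1
STAT3
STAT5A
STK11
TERT
TGFB1
TGFBR2
TLR4
TNF
TP53
TP63
TSC1
TSC2
TUBB
VEGFA
VHL
VIM
WNT1
WT1
XRCC1
YAP1
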