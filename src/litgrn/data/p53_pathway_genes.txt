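# Genes of the KEGG p53 signalling pathway (official symbols, uppercase).
CDKN2A
APAF1
ATM
AXIN1
BAK1
BAX
BCL2
BCL6
BIK
BIRC5
BRCA1
BUB1
CASP1
CASP8
CCNB1
CCND1
CCNG1
CDK2
CDK5
CDK9
CDKN1A
CFLAR
CHEK1
CHEK2
CNTN2
CRK
CSH2
DAXX
E2F1
EFEMP1
EGF
EIF2AK2
EP300
EPHA2
ETS1
FASN
FOXN3
GADD45A
H2AFX
HIPK2
IGFBP3
ING1
JUN
MAPK1
MAPK14
MAPK8
MAPK9
MDM2
MDM4
MTOR
MYC
MYCN
NANOG
PARP1
PCNA
PIN1
PMAIP1
PML
POLD1
PPM1D
PSMD10
PTEN
RCHY1
RHD
S100B
SERPINA2
SIRT1
STAT3
STK11
TNF
TNFRSF10A
TNFRSF10B
TNFSF10
TP53
TP73
UBE2S
YBX1
ZNF331
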