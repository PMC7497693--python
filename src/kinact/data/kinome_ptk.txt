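# Default kinome gene list: human protein tyrosine kinases plus the
# kinase/adaptor gene symbols carried by the tyrosine-kinase substrate
# peptides on the array. One HGNC symbol per line; '#' starts a comment.
ABL1
ABL2
ALK
AXL
BLK
BMX
BTK
CSF1R
CSK
DDR1
DDR2
EGFR
EPHA1
EPHA2
EPHA3
EPHA4
EPHA5
EPHA6
EPHA7
EPHA8
EPHA10
EPHB1
EPHB2
EPHB3
EPHB4
EPHB6
ERBB2
ERBB3
ERBB4
FER
FES
FGFR1
FGFR2
FGFR3
FGFR4
FGR
FLT1
FLT3
FLT4
FRK
FYN
HCK
IGF1R
INSR
INSRR
ITK
JAK1
JAK2
JAK3
KDR
KIT
LCK
LMTK2
LTK
LYN
MATK
MERTK
MET
MST1R
MUSK
NTRK1
NTRK2
NTRK3
PDGFRA
PDGFRB
PTK2
PTK2B
PTK6
PTK7
RET
ROR1
ROR2
ROS1
RYK
SRC
SRMS
SYK
TEC
TEK
TIE1
TNK1
TNK2
TXK
TYK2
TYRO3
YES1
ZAP70
# substrate-derived additions (non-PTK genes represented on the array)
BCKDHA
CD247
CDK2
CRK
EPB41
MAPK14
PDPK1
PIK3R1
PXN
SLC4A1
STAT4
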