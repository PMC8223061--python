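EYS
TNC
IMPG2
OAS1
EYA1
SFRP1
KCNA1
RBM24
KHDRBS2
NPR3
GAD1
NRL
PDLIM3
DKK2
WIF1
UNC5D
EOMES
HHIP
EMX2
ATOH1
MAB21L2
GABRA5
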