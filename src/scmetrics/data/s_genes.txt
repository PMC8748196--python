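MCM5
PCNA
TYMS
FEN1
MCM2
MCM4
RRM1
UNG
GINS2
MCM6
CDCA7
DTL
PRIM1
UHRF1
MLF1IP
HELLS
RFC2
RPA2
NASP
RAD51AP1
GMNN
WDR76
SLBP
CCNE2
UBR7
POLD3
MSH2
ATAD2
RAD51
RRM2
CDC45
CDC6
EXO1
TIPIN
DSCC1
BLM
CASP8AP2
USP1
CLSPN
POLA1
CHAF1B
BRIP1
E2F8
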