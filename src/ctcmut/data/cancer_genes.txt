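ARID1A
ASXL1
ATM
CREBBP
EP300
ERBB2
FGFR3
KDM6A
KMT2C
KMT2D
NOTCH1
PIK3CA
RB1
SETBP1
STAG2
TET1
TP53
TSC1
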