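# Genes associated with distal-onset muscular dystrophies
# (distal-only genes plus genes associated with both onsets)
CRYAB
DNM2
FHL1
FLNC
GNE
LDB3
MATR3
MYH7
NEB
PNPLA2
VCP
ANO5
CAV3
DES
DNAJB6
DYSF
MYOT
TTN
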