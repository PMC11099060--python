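# Genes associated with proximal-onset (limb-girdle) muscular dystrophies
# (proximal-only genes plus genes associated with both onsets)
BVES
CAPN3
DAG1
FKRP
FKTN
GAA
GMPPB
HNRNPDL
LMNA
PLEC
POMGNT1
POMT1
POMT2
SGCA
SGCB
SGCD
SGCG
TCAP
TNPO3
TOR1AIP1
TRAPPC11
TRIM32
ANO5
CAV3
DES
DNAJB6
DYSF
MYOT
TTN
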