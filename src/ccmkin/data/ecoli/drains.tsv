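precursor
G6P
F6P
GAP
PEP
PYR
AcCoA
aKG
SUC
FUM
OAA
R5P
E4P
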