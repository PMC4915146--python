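name	value
X	0.0015
GLC	0.05
G6P	1.5
F6P	0.45
FBP	3.0
GAP	0.35
PG3	1.5
PEP	0.45
PYR	1.0
AcCoA	0.55
ACP	0.12
ACE	0.02
ICIT	0.1
GOX	0.01
aKG	0.5
SUC	0.55
FUM	0.3
MAL	1.6
OAA	0.1
GL6P	0.05
PG6	0.8
KDPG	0.12
RU5P	0.3
R5P	0.45
X5P	0.3
S7P	0.3
E4P	0.12
cAMP	0.05
E_Glk	0.0006
E_Pfk	0.0006
E_Fbp	0.0006
E_Gapdh	0.0006
E_Pyk	0.0006
E_Pps	0.0006
E_Pdh	0.0006
E_Pta	0.0006
E_Ack	0.0006
E_Acs	0.0006
E_Cs	0.0006
E_Icdh	0.0006
E_akgdh	0.0006
E_Sdh	0.0006
E_Fum	0.0006
E_Mdh	0.0006
E_Icl	0.0006
E_Ms	0.0006
E_Mez	0.0006
E_Pck	0.0006
E_Ppc	0.0006
EIIA	0.003
GLCex	22.2
ACEex	0.0
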