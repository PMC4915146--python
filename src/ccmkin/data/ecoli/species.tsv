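name	role	display_name
GLC	metabolite	GLC
G6P	metabolite	G6P
F6P	metabolite	F6P
FBP	metabolite	FBP
GAP	metabolite	GAP
PG3	metabolite	3PG
PEP	metabolite	PEP
PYR	metabolite	PYR
AcCoA	metabolite	AcCoA
ACP	metabolite	AcP
ACE	metabolite	ACE
ICIT	metabolite	ICIT
GOX	metabolite	GOX
aKG	metabolite	aKG
SUC	metabolite	SUC
FUM	metabolite	FUM
MAL	metabolite	MAL
OAA	metabolite	OAA
GL6P	metabolite	6PGL
PG6	metabolite	6PG
KDPG	metabolite	KDPG
RU5P	metabolite	RU5P
R5P	metabolite	R5P
X5P	metabolite	X5P
S7P	metabolite	S7P
E4P	metabolite	E4P
cAMP	metabolite	cAMP
E_Glk	enzyme	Glk
E_Pfk	enzyme	Pfk
E_Fbp	enzyme	Fbp
E_Gapdh	enzyme	Gapdh
E_Pyk	enzyme	Pyk
E_Pps	enzyme	Pps
E_Pdh	enzyme	Pdh
E_Pta	enzyme	Pta
E_Ack	enzyme	Ack
E_Acs	enzyme	Acs
E_Cs	enzyme	Cs
E_Icdh	enzyme	Icdh
E_akgdh	enzyme	akgdh
E_Sdh	enzyme	Sdh
E_Fum	enzyme	Fum
E_Mdh	enzyme	Mdh
E_Icl	enzyme	Icl
E_Ms	enzyme	Ms
E_Mez	enzyme	Mez
E_Pck	enzyme	Pck
E_Ppc	enzyme	Ppc
EIIA	pts_protein	EIIA
GLCex	extracellular	glucose(ext)
ACEex	extracellular	acetate(ext)
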