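reaction	species	coeff
Pts4	GLCex	-1.0
Pts4	PEP	-1.0
Pts4	G6P	1.0
Pts4	PYR	1.0
Nonpts	GLCex	-1.0
Nonpts	GLC	1.0
Glk	GLC	-1.0
Glk	G6P	1.0
Pgi	G6P	-1.0
Pgi	F6P	1.0
Pfk	F6P	-1.0
Pfk	FBP	1.0
Fbp	FBP	-1.0
Fbp	F6P	1.0
Fba	FBP	-1.0
Fba	GAP	2.0
Gapdh	GAP	-1.0
Gapdh	PG3	1.0
Eno	PG3	-1.0
Eno	PEP	1.0
Pyk	PEP	-1.0
Pyk	PYR	1.0
Pps	PYR	-1.0
Pps	PEP	1.0
Pdh	PYR	-1.0
Pdh	AcCoA	1.0
Pta	AcCoA	-1.0
Pta	ACP	1.0
Ack	ACP	-1.0
Ack	ACE	1.0
Acs	ACE	-1.0
Acs	AcCoA	1.0
ACEtr	ACE	-1.0
ACEtr	ACEex	1.0
Cs	OAA	-1.0
Cs	AcCoA	-1.0
Cs	ICIT	1.0
Icdh	ICIT	-1.0
Icdh	aKG	1.0
akgdh	aKG	-1.0
akgdh	SUC	1.0
Sdh	SUC	-1.0
Sdh	FUM	1.0
Fum	FUM	-1.0
Fum	MAL	1.0
Mdh	MAL	-1.0
Mdh	OAA	1.0
Icl	ICIT	-1.0
Icl	SUC	1.0
Icl	GOX	1.0
Ms	GOX	-1.0
Ms	AcCoA	-1.0
Ms	MAL	1.0
Mez	MAL	-1.0
Mez	PYR	1.0
Pck	OAA	-1.0
Pck	PEP	1.0
Ppc	PEP	-1.0
Ppc	OAA	1.0
G6pdh	G6P	-1.0
G6pdh	GL6P	1.0
Pgl	GL6P	-1.0
Pgl	PG6	1.0
6pgdh	PG6	-1.0
6pgdh	RU5P	1.0
Ru5p	RU5P	-1.0
Ru5p	X5P	1.0
R5PI	RU5P	-1.0
R5PI	R5P	1.0
TktA	R5P	-1.0
TktA	X5P	-1.0
TktA	S7P	1.0
TktA	GAP	1.0
Tal	S7P	-1.0
Tal	GAP	-1.0
Tal	F6P	1.0
Tal	E4P	1.0
TktB	X5P	-1.0
TktB	E4P	-1.0
TktB	F6P	1.0
TktB	GAP	1.0
Edd	PG6	-1.0
Edd	KDPG	1.0
Eda	KDPG	-1.0
Eda	GAP	1.0
Eda	PYR	1.0
Cya	cAMP	1.0
PrtRec	aKG	1.0
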