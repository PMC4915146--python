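name	expression
EIIAP	EIIA * PEP / (PEP + K_EIIA_r * PYR + K_EIIA_0)
Crp_cAMP	Crp_total * cAMP / (cAMP + K_Crp_cAMP)
Crp	Crp_total - Crp_cAMP
Cra_FBP	Cra_total * FBP / (FBP + K_Cra_FBP)
Cra	Cra_total - Cra_FBP
PdhR_PYR	PdhR_total * PYR / (PYR + K_PdhR_PYR)
PdhR	PdhR_total - PdhR_PYR
IclR	IclR_total
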