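name	kind	enzyme	gene	reversible	expression
Pts4	metabolic	EIIA	ptsG	0	v_Pts4_max * (GLCex / (GLCex + K_Pts_GLC)) * (EIIAP / (EIIAP + K_Pts_EIIAP))
Nonpts	metabolic		galP	0	v_Nonpts_max * GLCex / (GLCex + K_Nonpts_GLC)
Glk	metabolic	E_Glk	glk	0	k_Glk_cat * E_Glk * GLC / (GLC + K_Glk_GLC)
Pgi	metabolic		pgi	1	v_Pgi_max * (G6P - F6P / Keq_Pgi) / (K_Pgi_G6P * (1 + PG6 / K_Pgi_G6P_6pginh) + G6P + F6P * K_Pgi_G6P / K_Pgi_F6P)
Pfk	metabolic	E_Pfk	pfkA	0	k_Pfk_cat * E_Pfk * F6P / (F6P + K_Pfk_F6P) / (1 + PEP / K_Pfk_PEP)
Fbp	metabolic	E_Fbp	fbp	0	k_Fbp_cat * E_Fbp * FBP / (FBP + K_Fbp_FBP) * (a_Fbp + (1 - a_Fbp) * PEP / (PEP + K_Fbp_PEP))
Fba	metabolic		fbaA	1	v_Fba_max * (FBP - GAP**2 / Keq_Fba) / (K_Fba_FBP + FBP + GAP**2 / K_Fba_GAP)
Gapdh	metabolic	E_Gapdh	gapA	1	k_Gapdh_cat * E_Gapdh * (GAP - PG3 / Keq_Gapdh) / (K_Gapdh_GAP + GAP + PG3 * K_Gapdh_GAP / K_Gapdh_PG3)
Eno	metabolic		eno	1	v_Eno_max * (PG3 - PEP / Keq_Eno) / (K_Eno_PG3 + PG3 + PEP * K_Eno_PG3 / K_Eno_PEP)
Pyk	metabolic	E_Pyk	pykF	0	k_Pyk_cat * E_Pyk * PEP / (PEP + K_Pyk_PEP_s) * (a_Pyk + (1 - a_Pyk) * FBP / (FBP + K_Pyk_FBP))
Pps	metabolic	E_Pps	pps	0	k_Pps_cat * E_Pps * PYR / (PYR + K_Pps_PYR)
Pdh	metabolic	E_Pdh	aceE	0	k_Pdh_cat * E_Pdh * PYR / (PYR + K_Pdh_PYR) / (1 + AcCoA / K_Pdh_AcCoA)
Pta	metabolic	E_Pta	pta	1	k_Pta_cat * E_Pta * (AcCoA - ACP / Keq_Pta) / (K_Pta_AcCoA + AcCoA + ACP * K_Pta_AcCoA / K_Pta_ACP)
Ack	metabolic	E_Ack	ackA	1	k_Ack_cat * E_Ack * (ACP - ACE / Keq_Ack) / (K_Ack_ACP + ACP + ACE * K_Ack_ACP / K_Ack_ACE)
Acs	metabolic	E_Acs	acs	0	k_Acs_cat * E_Acs * ACE / (ACE + K_Acs_ACE_m)
ACEtr	transport			1	k_ACEtr * (ACE - ACEex)
Cs	metabolic	E_Cs	gltA	0	k_Cs_cat * E_Cs * OAA * AcCoA / ((OAA + K_Cs_OAA) * (AcCoA + K_Cs_AcCoA)) / (1 + aKG / K_Cs_aKG)
Icdh	metabolic	E_Icdh	icd	0	k_Icdh_cat * E_Icdh * ICIT / (ICIT + K_Icdh_ICIT) / (1 + cAMP / K_Icdh_cAMP)
akgdh	metabolic	E_akgdh	sucA	0	k_akgdh_cat * E_akgdh * aKG / (aKG + K_akgdh_aKG)
Sdh	metabolic	E_Sdh	sdhC	1	E_Sdh * (k_Sdh1_cat * SUC / K_Sdh_SUC - k_Sdh2_cat * FUM / K_Sdh_FUM) / (1 + SUC / K_Sdh_SUC + FUM / K_Sdh_FUM)
Fum	metabolic	E_Fum	fumA	1	E_Fum * (k_Fum1_cat * FUM / K_Fum_FUM - k_Fum2_cat * MAL / K_Fum_MAL) / (1 + FUM / K_Fum_FUM + MAL / K_Fum_MAL)
Mdh	metabolic	E_Mdh	mdh	1	E_Mdh * (k_Mdh1_cat * MAL / K_Mdh_MAL - k_Mdh2_cat * OAA / K_Mdh_OAA) / (1 + MAL / K_Mdh_MAL + OAA / K_Mdh_OAA)
Icl	metabolic	E_Icl	aceA	0	k_Icl_cat * E_Icl * ICIT / (ICIT + K_Icl_ICIT) / (1 + PEP / K_Icl_PEP + PG3 / K_Icl_3PG + aKG / K_Icl_aKG)
Ms	metabolic	E_Ms	aceB	0	k_Ms_cat * E_Ms * GOX * AcCoA / ((GOX + K_Ms_GOX) * (AcCoA + K_Ms_AcCoA))
Mez	metabolic	E_Mez	maeB	0	k_Mez_cat * E_Mez * MAL / (MAL + K_Mez_MAL) / (1 + AcCoA / K_Mez_AcCoA + cAMP / K_Mez_cAMP)
Pck	metabolic	E_Pck	pck	0	k_Pck_cat * E_Pck * OAA / (OAA + K_Pck_OAA)
Ppc	metabolic	E_Ppc	ppc	0	k_Ppc_cat * E_Ppc * PEP / (PEP + K_Ppc_PEP) * (a_Ppc + (1 - a_Ppc) * FBP / (FBP + K_Ppc_FBP))
G6pdh	metabolic		zwf	0	v_G6pdh_max * G6P / (G6P + K_G6pdh_G6P)
Pgl	metabolic		pgl	0	v_Pgl_max * GL6P / (GL6P + K_Pgl_GL6P)
6pgdh	metabolic		gnd	0	v_6pgdh_max * PG6 / (PG6 + K_6pgdh_PG6)
Ru5p	metabolic		rpe	1	v_Ru5p_max * (RU5P - X5P / Keq_Ru5p) / (K_Ru5p + RU5P + X5P)
R5PI	metabolic		rpiA	1	v_R5PI_max * (RU5P - R5P / Keq_R5PI) / (K_R5PI + RU5P + R5P)
TktA	metabolic		tktA	1	v_TktA_max * (R5P * X5P - S7P * GAP / Keq_TktA) / (K_TktA + R5P * X5P + S7P * GAP)
Tal	metabolic		talB	1	v_Tal_max * (S7P * GAP - F6P * E4P / Keq_Tal) / (K_Tal + S7P * GAP + F6P * E4P)
TktB	metabolic		tktB	1	v_TktB_max * (X5P * E4P - F6P * GAP / Keq_TktB) / (K_TktB + X5P * E4P + F6P * GAP)
Edd	metabolic		edd	0	v_Edd_max * PG6 / (PG6 + K_Edd_PG6)
Eda	metabolic		eda	0	v_Eda_max * KDPG / (KDPG + K_Eda_KDPG)
Cya	metabolic		cyaA	1	v_Cya_max * EIIAP**2 / (EIIAP**2 + K_Cya_EIIAP**2) - k_cAMP_deg * cAMP
AceK_ki	metabolic		aceK	0	v_AceK_max * ACE / (ACE + K_AceK_ACE)
PrtRec	transport			0	n_rec * k_deg_prot * (E_Glk + E_Pfk + E_Fbp + E_Gapdh + E_Pyk + E_Pps + E_Pdh + E_Pta + E_Ack + E_Acs + E_Cs + E_Icdh + E_akgdh + E_Sdh + E_Fum + E_Mdh + E_Icl + E_Ms + E_Mez + E_Pck + E_Ppc + EIIA) / rho_cyt
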