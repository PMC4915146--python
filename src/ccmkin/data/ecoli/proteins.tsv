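species	regulated	synthesis
E_Glk	1	k_s_Glk * (b_grep + (1 - b_grep) * K_g_cra_rep / (K_g_cra_rep + Cra)) - k_deg_prot * E_Glk
E_Pfk	1	k_s_Pfk * (b_grep + (1 - b_grep) * K_g_cra_rep / (K_g_cra_rep + Cra)) - k_deg_prot * E_Pfk
E_Gapdh	1	k_s_Gapdh * (b_grep + (1 - b_grep) * K_g_cra_rep / (K_g_cra_rep + Cra)) - k_deg_prot * E_Gapdh
E_Pyk	1	k_s_Pyk * (b_grep + (1 - b_grep) * K_g_cra_rep / (K_g_cra_rep + Cra)) - k_deg_prot * E_Pyk
E_Pdh	1	k_s_Pdh * (b_grep + (1 - b_grep) * K_g_pdhr / (K_g_pdhr + PdhR)) - k_deg_prot * E_Pdh
E_Pta	1	k_s_Pta * (b_grep + (1 - b_grep) * K_g_pdhr / (K_g_pdhr + PdhR)) - k_deg_prot * E_Pta
E_Ack	1	k_s_Ack * (b_grep + (1 - b_grep) * K_g_pdhr / (K_g_pdhr + PdhR)) - k_deg_prot * E_Ack
E_Fbp	1	k_s_Fbp * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Fbp
E_Pps	1	k_s_Pps * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Pps
E_Pck	1	k_s_Pck * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Pck
E_Mez	1	k_s_Mez * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Mez
E_Cs	1	k_s_Cs * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Cs
E_Icdh	1	k_s_Icdh * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Icdh
E_akgdh	1	k_s_akgdh * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_akgdh
E_Sdh	1	k_s_Sdh * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Sdh
E_Fum	1	k_s_Fum * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Fum
E_Mdh	1	k_s_Mdh * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) - k_deg_prot * E_Mdh
E_Icl	1	k_s_Icl * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) * (K_g_iclr / (K_g_iclr + IclR)) - k_deg_prot * E_Icl
E_Ms	1	k_s_Ms * (b_gact + (1 - b_gact) * Crp_cAMP / (Crp_cAMP + K_g_crp)) * (b_gact + (1 - b_gact) * Cra / (Cra + K_g_cra_act)) * (K_g_iclr / (K_g_iclr + IclR)) - k_deg_prot * E_Ms
E_Acs	1	k_s_Acs * (b_gact + (1 - b_gact) * Crp_cAMP**2 / (Crp_cAMP**2 + K_g_crp_acs**2)) - k_deg_prot * E_Acs
E_Ppc	1	k_s_Ppc - k_deg_prot * E_Ppc
EIIA	0	k_s_EIIA - k_deg_prot * EIIA
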