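# Reference survey of alkyltrimethylammonium-alkylsulfate (CmTMA+/CnS-) bilayer
# systems at 298 K: composition arithmetic, per-system structural/mechanical
# properties, and experimental main transition temperatures (NA where not
# reported).  Columns: m, n, abbreviation, total_carbons, delta_c,
# a_ipa_nm2, k_a_mN_m, chi_tilt_J_mol_deg2, kc_eff_kBT, abs_scd,
# gauche_fraction, t_m_K.
m	n	abbreviation	total_carbons	delta_c	a_ipa_nm2	k_a_mN_m	chi_tilt_J_mol_deg2	kc_eff_kBT	abs_scd	gauche_fraction	t_m_K
16	16	HTMA-HS	32	-1	0.425	1835.75	99.56	75.62	0.333	0.034	338.28
16	14	HTMA-TS	30	1	0.428	716.70	92.85	78.00	0.305	0.053	339.83
16	12	HTMA-DS	28	3	0.428	1701.20	42.72	51.93	0.381	0.093	327.09
16	10	HTMA-DeS	26	5	0.476	225.76	8.55	17.29	0.289	0.171	NA
14	16	TTMA-HS	30	-3	0.420	1797.40	30.72	57.59	0.385	0.065	NA
14	14	TTMA-TS	28	-1	0.427	1623.82	37.86	60.71	0.380	0.081	328.28
14	12	TTMA-DS	26	1	0.420	1373.57	59.55	54.05	0.387	0.090	332.80
14	10	TTMA-DeS	24	3	0.486	521.80	8.14	14.12	0.285	0.183	NA
12	16	DTMA-HS	28	-5	0.430	730.84	23.45	34.02	0.375	0.112	NA
12	14	DTMA-TS	26	-3	0.431	1301.73	32.85	39.03	0.372	0.111	320.05
12	12	DTMA-DS	24	-1	0.440	995.82	24.53	39.67	0.371	0.143	314.52
12	10	DTMA-DeS	22	1	0.492	457.74	8.18	10.85	0.281	0.192	NA
10	16	DeTA-HS	26	-7	0.495	370.90	5.68	4.40	0.270	0.205	NA
10	14	DeTA-TS	24	-5	0.499	379.41	6.71	7.83	0.271	0.205	303.71
10	12	DeTA-DS	22	-3	0.499	481.92	8.24	9.67	0.270	0.207	304.06
10	10	DeTA-DeS	20	-1	0.500	451.00	7.14	7.94	0.267	0.212	NA
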