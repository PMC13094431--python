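polarity	desi_avg_mz	desi_between_rep_ppm	annotation	desi_adduct	other_adducts_enriched	avg_intensity_adipose	avg_intensity_nonadipose	avg_fold_change	avg_roc	lesa_observed_ms1	dominant_fa_composition	lesa_adduct	other_adducts_detected	lipid_class	lesa_delta_ppm
+	549.49	0.60	DG(32:1)	[M + H-H2O]+	[M+H]+	1.71E+04	9.09E+03	1.88	0.76	549.4861	16:0_16:1	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	2.91
+	551.50	0.46	DG(32:0)	[M + H-H2O]+	[M+Na]+	4.92E+04	2.73E+04	1.80	0.77	551.5008	16:0_16:0	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	4.71
+	573.49	0.34	DG(34:3)	[M + H-H2O]+	[M+H]+, [M+Na]+	1.63E+04	8.51E+03	1.92	0.76	573.487	16:1_18:2	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	1.22
+	575.50	0.50	DG(34:2)	[M + H-H2O]+	[M+H]+, [M+Na]+	9.49E+04	4.91E+04	1.93	0.79	575.5008	16:0_18:2	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	4.52
+	577.53	0.26	DG(34:1)	[M + H-H2O]+	[M+Na]+	1.29E+05	6.74E+04	1.92	0.80	577.519	16:0_18:1	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	0.00
+	579.54	0.44	DG(34:0)	[M + H-H2O]+	[M+H]+	1.53E+04	8.25E+03	1.86	0.78	579.5322	16:0_18:0	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	4.31
+	599.51	0.59	DG(36:4)	[M + H-H2O]+	[M+H]+, [M+Na]+	3.80E+04	1.81E+04	2.10	0.83	599.5033	18:2_18:2	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	0.17
+	601.52	0.34	DG(36:3)	[M + H-H2O]+	[M+H]+, [M+Na]+	8.39E+04	4.23E+04	1.98	0.79	601.5189	18:1_18:2	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	0.17
+	603.54	0.57	DG(36:2)	[M + H-H2O]+	[M+Na]+	6.11E+04	3.09E+04	1.98	0.80	603.5314	18:1_18:1	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	5.47
+	605.56	0.49	DG(36:1)	[M + H-H2O]+	[M+H]+	1.38E+04	7.23E+03	1.91	0.77	605.547	18:0_18:1	[M + H-H2O]+	[M+H]+, [M+Na]+	DG	5.45
+	827.71	1.43	TG(48:1)	[M+Na]+	[M + NH4]+	1.46E+04	6.78E+03	2.15	0.76	827.71	14:0_16:0_18:1	[M+Na]+	[M + NH4]+	TG	-0.12
+	849.70	2.67	TG(50:4)	[M+Na]+	-	1.22E+04	6.69E+03	1.82	0.73	849.694	14:0_18:2_18:2	[M+Na]+	[M + NH4]+	TG	0.35
+	851.72	1.49	TG(50:3)	[M+Na]+	-	4.77E+04	1.77E+04	2.69	0.85	851.7096	16:0_16:1_18:2	[M+Na]+	[M + NH4]+	TG	0.35
+	853.73	0.59	TG(50:2)	[M+Na]+	[M + NH4]+	1.25E+05	4.98E+04	2.52	0.89	853.7255	16:0_16:0_18:2	[M+Na]+	[M + NH4]+	TG	1.17
+	854.55	0.72	PC(40:7)	[M+Na]+	[M + NH4]+	6.27E+04	2.47E+04	2.53	0.88	854.5674	20:3_20:4	[M+Na]+	[M+H]+, [M + NH4]+	PC	2.34
+	855.76	0.72	TG(50:1)	[M+Na]+	[M + NH4]+	1.22E+05	5.07E+04	2.40	0.88	855.7416	16:0_16:0_18:1	[M+Na]+	[M + NH4]+	TG	-4.67
+	856.57	0.43	PC(40:6)	[M+Na]+	[M + NH4]+	5.71E+04	2.36E+04	2.42	0.88	856.5827	20:3_20:3	[M+Na]+	[M+H]+, [M + NH4]+	PC	1.87
+	857.76	0.88	TG(50:0)	[M+Na]+	[M + NH4]+	2.72E+04	1.20E+04	2.26	0.80	857.7504	16:0_16:0_18:0	[M+Na]+	[M + NH4]+	TG	4.43
+	873.70	2.07	TG(52:6)	[M+Na]+	[M + NH4]+	7.45E+04	3.57E+04	2.09	0.80	873.694	16:0_18:3_18:3	[M+Na]+	[M+H]+, [M + NH4]+	TG	0.23
+	875.72	2.55	TG(52:5)	[M+Na]+	[M + NH4]+	3.18E+04	1.57E+04	2.02	0.76	875.7099	16:0_18:2_18:3	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.11
+	877.71	3.59	TG(52:4)	[M+Na]+	[M + NH4]+	1.57E+05	6.03E+04	2.60	0.88	877.7254	16:0_18:2_18:2	[M+Na]+	[M + NH4]+	TG	0.18
+	881.76	1.84	TG(52:2)	[M+Na]+	[M + NH4]+	1.82E+05	7.12E+04	2.55	0.90	881.7574	16:0_18:1_18:1	[M+Na]+	[M + NH4]+	TG	-1.29
+	883.77	2.60	TG(52:1)	[M+Na]+	[M + NH4]+	7.40E+04	2.98E+04	2.48	0.85	883.7739	16:0_18:0_18:1	[M+Na]+	[M + NH4]+	TG	-1.58
+	891.73	1.10	TG (53:4)	[M+Na]+	[M+H]+, [M + NH4]+	3.68E+04	1.76E+04	2.09	0.78	891.7414	17:0_18:2_18:2	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.22
+	897.72	4.77	TG(54:8)	[M+Na]+	[M+H]+, [M + NH4]+	1.13E+05	5.87E+04	1.92	0.78	897.6957	18:2_18:3_18:3	[M+Na]+	[M+H]+, [M + NH4]+	TG	-1.56
+	901.75	2.82	TG(54:6)	[M+Na]+	[M + NH4]+	8.01E+04	2.85E+04	2.81	0.78	901.7253	18:1_18:2_18:3	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.22
+	903.76	2.65	TG (54:5)	[M+Na]+	[M+H]+, [M + NH4]+	1.42E+05	5.12E+04	2.77	0.89	903.7412	18:1_18:2_18:2	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.22
+	905.77	3.67	TG(54:4)	[M+Na]+	[M + NH4]+	1.48E+05	5.46E+04	2.71	0.90	905.7571	18:1_18:1_18:2	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.22
+	907.78	2.63	TG (54:3)	[M+Na]+	[M + NH4]+	5.99E+04	2.37E+04	2.53	0.82	907.7733	18:0_18:1_18:2	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.88
+	913.74	1.06	TG(55:7)	[M+Na]+	[M+H]+, [M + NH4]+	3.72E+04	1.86E+04	2.00	0.73	913.7271	17:0_18:2_20:5	[M+Na]+	[M+H]+	TG	-1.64
+	925.76	2.02	TG(56:8)	[M+Na]+	[M+H]+	3.02E+04	1.26E+04	2.39	0.77	925.7253	16:0_18:2_22:6	[M+Na]+	[M+H]+, [M + NH4]+	TG	-0.32
+	927.77	2.84	TG(56:7)	[M+Na]+	[M+H]+	2.25E+04	9.04E+03	2.49	0.62	927.7416	16:0_18:1_22:6	[M+Na]+	[M+Na]+	TG	0.43
+	929.79	2.93	TG(56:6)	[M+Na]+	[M+H]+	6.15E+03	5.24E+03	1.17	0.61	929.7601	18:1_18:2_20:3	[M+Na]+	[M+Na]+	TG	3.44
+	935.79	0.55	TG(56:3)	[M+Na]+	[M+H]+	3.16E+04	1.35E+04	2.35	0.74	935.8098	18:1_18:1_20:1	[M+Na]+	[M + NH4]+	TG	-6.41
+	937.78	3.27	TG(56:2)	[M+Na]+	-	2.92E+04	1.30E+04	2.25	0.73	937.8195	18:0_18:1_20:1	[M+Na]+	[M+H]+, [M + NH4]+	TG	0.00
-	199.17	0.68	FA (12:0)	[M-H]-	-	6.13E+03	2.51E+03	2.45	0.83	199.1699	-	[M-H]-	-	FA	-2.51
-	227.20	0.53	FA (14:0)	[M-H]-	-	2.29E+03	1.26E+03	1.82	0.79	227.2035	-	[M-H]-	-	FA	7.92
-	251.20	0.63	FA (16:2)	[M-H]-	-	4.12E+02	2.43E+02	1.70	0.76	251.2013	-	[M-H]-	-	FA	-0.79
-	253.22	0.20	FA (16:1)	[M-H]-	-	9.24E+02	5.25E+02	1.76	0.82	253.2171	-	[M-H]-	-	FA	-0.79
-	255.23	0.41	FA (16:0)	[M-H]-	-	8.78E+04	4.63E+04	1.89	0.89	255.2324	-	[M-H]-	-	FA	-2.35
-	267.20	1.24	FA (16:2;O)	[M-H]-	-	1.72E+03	8.79E+02	1.95	0.72	267.1961	-	[M-H]-	-	FA	-1.87
-	267.23	0.28	FA (17:1)	[M-H]-	-	3.12E+03	2.06E+03	1.51	0.74	267.2327	-	[M-H]-	-	FA	-1.12
-	269.21	0.35	FA (17:0)	[M-H]-	-	2.14E+04	9.23E+03	2.32	0.92	269.2483	-	[M-H]-	-	FA	-1.11
-	271.23	1.22	FA (16:0;O)	[M-H]-	-	2.09E+03	1.17E+03	1.79	0.83	271.2275	-	[M-H]-	-	FA	-1.47
-	283.27	1.13	FA (18:0)	[M-H]-	-	2.15E+05	1.04E+05	2.07	0.91	283.2641	-	[M-H]-	-	FA	-0.71
-	295.23	0.19	FA (18:2;O)	[M-H]-	-	2.80E+03	1.32E+03	2.12	0.86	295.2275	-	[M-H]-	-	FA	-1.35
-	297.24	1.58	FA (18:1;O)	[M-H]-	-	2.26E+04	9.34E+03	2.42	0.97	297.2432	-	[M-H]-	-	FA	-1.01
-	311.30	1.40	FA (20:0)	[M-H]-	-	4.27E+05	1.94E+05	2.20	0.96	311.2952	-	[M-H]-	-	FA	-1.28
-	339.33	1.37	FA (22:0)	[M-H]-	-	1.93E+05	8.59E+04	2.25	0.90	339.3263	-	[M-H]-	-	FA	-1.77
-	343.22	0.28	FA (22:6;O)	[M-H]-	-	1.99E+03	1.37E+03	1.45	0.67	343.227	-	[M-H]-	-	FA	-2.62
-	367.36	0.24	FA (24:0)	[M-H]-	-	3.20E+04	1.38E+04	2.32	0.91	367.3575	-	[M-H]-	-	FA	-1.91
-	452.27	1.82	LPE (16:0)	[M-H]-	-	1.15E+03	5.39E+02	2.14	0.82	452.277	-	[M-H]-	-	LPE	-2.87
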