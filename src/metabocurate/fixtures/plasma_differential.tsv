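name	rt_min	formula	adduct	observed_mz	calculated_mz	error_ppm	median_basal_e4	iqr_basal_e4	median_day7_e4	iqr_day7_e4	fc	p_value	fdr
1-(4-methylsulfanylphenyl)-3-phenylurea	8.378	C14H14N2OS	[M+Na]+	517.17255	517.17267	−0.2	0.07	0.00	1.86	0.10	21.5	0.005	0.017
LPC O-13:1	10.451	C21H44NO6P	[M+H]+	438.29791	438.29791	0.0	0.17	0.00	1.36	0.23	7.5	0.005	0.017
1-(2-Hydroxyethyl)-2,2,6,6-tetramethyl-4-piperidinol	1.224	C11H23NO2	[M+H]+	202.18022	202.18021	0.0	0.23	0.00	1.76	0.30	6.9	0.005	0.017
1,2,3,4-Tetrahydro-b-carboline	3.460	C11H12N2	[M+H]+	173.10725	173.10730	−0.3	0.22	0.00	1.34	0.32	6.0	0.005	0.017
PC (18:0/22:6)	12.403	C48H84NO8P	[M+H]+	834.60095	834.60071	0.3	0.20	0.00	0.70	0.19	5.5	0.005	0.017
13-hydroperoxy-1-piperidin-1-ylicosa-2,4,14-trien-1-one	12.591	C25H43NO3	[M+Na]+	406.32959	406.33099	−3.4	1.03	0.00	5.31	0.81	4.6	0.005	0.017
D-erythro-N-stearoylsphingosine	8.203	C18H37NO2	[M+H]+	300.28961	300.28970	−0.3	0.40	0.00	1.16	0.50	4.1	0.005	0.017
DGGA 13:0/27:0	5.913	C49H92O11	[M+H]+	874.69995	874.69781	2.4	0.28	0.00	0.88	0.12	3.8	0.005	0.017
Glucose	2.619	C6H12O6	[M+K]+	181.07214	181.07204	0.6	0.32	0.00	1.13	0.15	3.8	0.005	0.017
Docosahexaenoic acid methyl ester	12.889	C23H34O2	[M+H]+	343.26376	343.26321	1.6	0.32	0.00	1.19	0.06	3.5	0.005	0.017
NAGlySer 26:7/17:2	11.875	C48H74N2O7	[M+H]+	808.58398	808.58344	0.7	0.74	0.00	2.13	1.03	3.0	0.019	0.050
Theobromine	2.391	C7H8N4O2	[M+H]+	181.07225	181.07204	1.2	8.12	0.00	24.5	2.30	2.9	0.005	0.017
N-Isovaleroylglycine	2.376	C7H13NO3	[M+H]+	182.07898	182.07880	1.0	0.68	0.17	1.98	0.17	2.8	0.005	0.017
Tripropylene glycol	3.240	C9H20O4	[M+H]+	193.14313	193.14340	−1.4	0.52	1.42	2.86	0.75	2.7	0.016	0.045
Caffeine	3.064	C8H10N4O2	[M+H]+	195.08792	195.08771	1.1	4.91	0.00	12.0	0.55	2.5	0.005	0.017
Choline cation	0.569	C5H14NO	[Cat]+	104.10635	104.10700	−6.2	11.0	0.60	17.4	2.05	1.5	0.016	0.045
2-Methylisoquinolin-2-ium cation	2.131	C10H10N	[Cat−C2H3N]+	103.05445	103.05420	2.4	3.20	0.25	2.90	0.05	−1.1	0.016	0.045
Cytidine	0.981	C9H13N3O5	[M+H-C5H8O4]+	112.05074	112.05050	2.1	11.8	0.15	10.8	0.35	−1.1	0.009	0.027
Tyrosine	1.379	C9H11NO3	[M+H]+	182.08156	182.08141	0.8	9.29	0.30	6.12	0.42	−1.4	0.016	0.045
Asp-Lys	0.599	C10H19N3O5	[M+H]+	132.07436	132.07491	−4.2	8.21	0.52	5.42	0.69	−1.5	0.016	0.045
Creatine	0.716	C4H9N3O2	[M+NH4]+	132.07704	132.07727	−1.7	3.54	0.34	2.33	0.34	−1.5	0.016	0.045
7H-[1,2,4]Triazolo[4,3-b][1,2,4]triazole-3,7-diamine	0.648	C3H5N7	[M+Na]+	140.0679	140.06790	0.0	2.85	1.10	2.11	0.11	−1.5	0.009	0.027
Emetine N-oxide	0.612	C29H40N2O5	[M+H]+	249.15613	249.15414	8.0	6.46	0.30	3.88	0.40	−1.7	0.009	0.027
Carbamazepine 10,11-epoxide	1.516	C15H12N2O2	[M+H]+	236.07085	236.07060	1.1	1.45	0.06	0.63	0.00	−2.3	0.005	0.017
Leu-Ala	2.480	C9H16N2O2	[M+H]+	185.12831	185.12840	−0.5	1.04	0.07	0.44	0.00	−2.4	0.005	0.017
Quinoline	2.561	C9H7N	[M+H]+	130.0654	130.06512	2.2	1.09	0.04	0.40	0.00	−2.6	0.005	0.017
Spermidine	0.470	C7H19N3	[M+NH4]+	146.16516	146.16518	−0.1	1.95	0.46	0.76	0.00	−2.7	0.005	0.017
SPB 19:0;2O	7.998	C19H41NO2	[M+H]+	316.32098	316.32101	−0.1	1.06	0.23	0.41	0.00	−2.8	0.005	0.017
Uric acid	1.064	C5H4N4O3	[M+H]+	169.03545	169.03560	−0.9	1.45	0.33	0.48	0.00	−2.8	0.005	0.017
(2E,6E,12E)-19-(2-amino-2-oxoethyl)-9,11-dihydroxy-8-methoxy-10,12,14-trimethyl-15-oxohenicosa-2,6,12-trienedioic acid	10.604	C27H43NO9	[M+H]+	543.32605	543.32800	−3.6	1.15	0.07	0.38	0.00	−2.9	0.005	0.017
Corticosterone	5.798	C21H30O4	[M+Na]+	347.22122	347.22131	−0.3	2.10	0.25	0.74	0.00	−3.0	0.005	0.017
DL-Octopamine	1.377	C8H11NO2	[M+H-H2O]+	136.07574	136.07570	0.3	1.36	0.01	0.40	0.00	−3.3	0.005	0.017
5-S-Methylthioadenosine	2.576	C11H15N5O3S	[M+H]+	298.09634	298.09683	−1.6	0.95	0.20	0.29	0.00	−3.7	0.005	0.017
AUDA	5.668	C23H40N2O3	[M+H]+	216.1956	216.19580	−0.9	1.31	0.77	0.28	0.00	−4.2	0.005	0.017
(R)-Prunasin	3.286	C14H17NO6	[M+H]+	340.10226	340.10379	−4.5	0.83	0.53	0.26	0.00	−4.3	0.005	0.017
2,2,6,6-Tetramethyl-4-piperidinyl 2-methylacrylate	6.097	C13H23NO2	[M+NH4]+	226.18021	226.18021	0.0	5.22	3.65	0.98	0.00	−5.0	0.005	0.017
Leu-Pro	1.997	C11H20N2O3	[M+NH4]+	229.1545	229.15469	−0.8	1.37	0.15	0.25	0.00	−5.1	0.005	0.017
Jasminoside	6.098	C15H20O3	[M+Na]+	266.17273	266.17380	−4.0	3.54	1.24	0.59	0.00	−5.2	0.005	0.017
Kynurenine	2.096	C10H12N2O3	[M+NH4]+	209.09207	209.09207	0.0	1.50	0.55	0.25	0.00	−6.0	0.005	0.017
3-(4-hydroxy-3-methoxyphenyl)prop-2-enamide	3.386	C10H11NO3	[M+H]+	194.08073	194.08099	−1.3	1.11	0.39	0.19	0.00	−6.3	0.005	0.017
Diisooctyl phthalate	12.351	C24H38O4	[M+Na]+	408.30878	408.31079	−4.9	7.37	3.06	1.09	0.00	−6.3	0.005	0.017
2-(1′,2′,3′,4′-Tetrahydroxybutyl)quinoxaline	3.585	C12H14N2O4	[M+H]+	251.10272	251.10260	0.5	1.66	0.56	0.15	0.00	−10.1	0.005	0.017
Spiroxamine	9.949	C18H35NO2	[M+H]+	298.27356	298.27399	−1.4	1.60	1.24	0.12	0.00	−10.6	0.005	0.017
Cer 8:0;2O/14:0	9.918	C22H45NO3	[M+H]+	372.34747	372.34723	0.6	1.18	0.79	0.10	0.00	−14.5	0.005	0.017
1-(Cyclohexylmethyl)proline	5.505	C12H21NO2	[M+NH4]+	212.16447	212.16451	−0.2	1.75	2.03	0.11	0.00	−17.6	0.005	0.017
Sydonic acid	4.149	C15H22O4	[M+NH4]+	266.15985	266.16000	−0.6	1.91	0.45	0.09	0.00	−19.7	0.005	0.017
Adenine	4.149	C5H5N5	[M+Na]+	271.11545	271.11630	−3.1	1.74	0.41	0.08	0.00	−19.9	0.005	0.017
Icaridin	5.506	C12H23NO3	[M+H]+	230.17514	230.17509	0.2	3.79	4.19	0.22	0.00	−19.9	0.007	0.023
Pentyl-b-D-glucopyranoside	4.149	C11H22O6	[M+H]+	249.13336	249.13440	−4.2	3.14	1.39	0.13	0.00	−22.0	0.005	0.017
(2R)-N-(3-Ethoxypropyl)-2,4-dihydroxy-3,3-dimethylbutanamide	4.880	C11H23NO4	[M+H]+	216.15933	216.15939	−0.3	2.01	2.49	0.09	0.00	−25.7	0.005	0.017
7-Keto-8-aminopelargonic acid	3.563	C9H17NO3	[M+H]+	188.12801	188.12810	−0.5	5.46	7.53	0.19	0.00	−31.8	0.005	0.017
Phosphorylcholine	10.271	C5H14NO4P	[M+H]+	184.07349	184.07332	0.9	1.29	0.09	0.03	0.00	−45.1	0.005	0.017
Phosphocholine	10.093	C5H14NO4P	[M+H]+	184.073	184.07300	0.0	1.12	0.27	0.03	0.00	−48.1	0.005	0.017
Cer 8:1;2O/2:0	4.228	C10H19NO3	[M+H]+	202.14378	202.14377	0.0	1.62	1.81	0.03	0.00	−53.7	0.005	0.017
Triphenylphosphine oxide	6.829	C18H15OP	[M+H]+	279.09348	279.09329	0.7	1.05	1.97	0.02	0.00	−59.7	0.005	0.017
Cyclo(L-Leu-L-Pip-L-Aoe-D-Phe)	9.824	C31H44N4O6	[M+H]+	603.29346	603.29547	−3.3	2.34	0.27	0.04	0.00	−61.3	0.005	0.017
N-cis-Hexadec-9-enoyl-L-homoserine lactone	8.009	C20H35NO3	[M+H]+	338.26685	338.26901	−6.4	2.42	2.35	0.04	0.00	−65.0	0.005	0.017
Methyprylon	4.229	C10H17NO2	[M+H]+	184.13274	184.13280	−0.3	1.11	1.51	0.02	0.00	−74.2	0.005	0.017
Melophlin D/H/I/J	7.821	C20H35NO3	[M+Na]+	338.26645	338.26700	−1.6	1.43	1.54	0.02	0.00	−77.6	0.005	0.017
6-Oxooctadecanoic acid	8.010	C18H34O3	[M+H]+	316.28479	316.28461	0.6	3.60	3.53	0.04	0.00	−89.9	0.005	0.017
Palmitoleoyl ethanolamide	9.066	C18H35NO2	[M+NH4]+	280.26373	280.26349	0.9	5.11	5.48	0.05	0.00	−95.0	0.005	0.017
N-Acetylleucine	2.920	C8H15NO3	[M+H]+	174.11209	174.11230	−1.2	2.76	3.64	0.02	0.00	−120.3	0.005	0.017
PC O-18:1	12.398	C26H52NO7P	[M+H]+	522.35602	522.35541	1.2	2.59	0.86	0.02	0.00	−133.9	0.005	0.017
LPC 18:1	12.397	C26H52NO7P	[M+Na]+	544.3385	544.33734	2.1	2.35	0.56	0.02	0.00	−151.9	0.005	0.017
Linoleoylglycine	8.775	C20H35NO3	[M+Na]+	320.25613	320.25839	−7.1	2.48	2.77	0.01	0.00	−153.7	0.005	0.017
Oleamide	8.775	C18H35NO	[M+H-H2]+	280.26425	280.26349	2.7	6.13	6.71	0.02	0.00	−253.4	0.005	0.017
LPC 18:3-SN1	9.679	C26H48NO7P	[M+H]+	518.32361	518.32410	−0.9	0.78	0.22	0.00	0.00	−262.5	0.005	0.017
1-Myristoyl-sn-glycero-3-phosphocholine	9.571	C22H46NO7P	[M+H]+	468.30911	468.30850	1.3	0.88	0.22	0.00	0.00	−262.8	0.005	0.017
1-Oleoyl-sn-glycero-3-phosphocholine	12.196	C26H52NO7P	[M+H]+	522.35565	522.35541	0.5	1.50	0.18	0.01	0.00	−267.3	0.005	0.017
Neofusapyrone	11.065	C34H54O9	[M+H]+	571.35883	571.36292	−7.2	1.19	0.37	0.01	0.00	−294.0	0.005	0.017
LPC 16:0	11.556	C24H50NO7P	[M+Na]+	518.32312	518.32172	2.7	3.45	2.80	0.02	0.00	−308.4	0.005	0.017
LPC 15:0-SN1	10.589	C23H48NO7P	[M+H]+	482.32422	482.32413	0.2	1.14	0.27	0.00	0.00	−398.0	0.005	0.017
PC O-20:5	10.232	C28H48NO7P	[M+H]+	542.32288	542.32410	−2.2	2.89	0.37	0.00	0.00	−635.1	0.005	0.017
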