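repeat_id	length	orientation	in_master	m1_path	m2_path	s1_path	s2_path	m1	m2	s1	s2	rate_printed
SR1	392	+	1	contig2-SR1-contig3	contig41-SR1-contig42	contig2-SR1-contig42	contig41-SR1-contig3	413	347	12	57	12.13
SR2	278	+	1	contig3-SR2-contig4	contig33-SR2-contig34	contig3-SR2-contig34	contig33-SR2-contig4	379	395	2	2	0.50
SR3	238	+	1	contig4-SR3-contig5	contig38-SR3-contig37	contig4-SR3-contig37	contig38-SR3-contig5	357	408	23	60	12.82
SR4	210	+	1	contig5-SR4-contig6	contig10-SR4-contig11	contig5-SR4-contig11	contig10-SR4-contig6	381	459	3	3	0.65
SR5	385	-	1	contig17-SR5-contig18	contig29-SR5-contig38	contig17-SR5-contig38	contig29-SR5-contig18	465	481	1	9	1.84
SR6	191	+	1	contig24-SR6-contig25	contig38-SR6-contig39	contig24-SR6-contig39	contig38-SR6-contig25	483	389	0	6	1.23
SR7	377	+	1	contig36-SR7-contig37	contig42-SR7-contig43	contig36-SR7-contig43	contig42-SR7-contig37	404	392	2	12	2.88
SR8	181	+	1	contig18-SR8-contig19	contig45-SR8-contig46	contig18-SR8-contig46	contig45-SR8-contig19	530	375	0	0	0.00
SR9	448	-	1	contig20-SR9-contig21	contig26-SR9-contig25	contig20-SR9-contig25	contig26-SR9-contig21	400	421	1	2	0.47
SR10	128	-	1	contig21-SR10-contig22	contig48-SR10-contig47	contig21-SR10-contig47	contig48-SR10-contig22	462	339	0	0	0.00
SR11	136	-	1	contig12-SR11-contig13	contig23-SR11-contig22	contig12-SR11-contig22	contig23-SR11-contig13	520	423	0	1	0.19
SR12	337	+	1	contig9-SR12-contig10	contig23-SR12-contig24	contig9-SR12-contig24	contig23-SR12-contig10	406	430	2	51	10.60
SR13	475	+	1	contig14-SR13-contig15	contig40-SR13-contig41	contig14-SR13-contig41	contig40-SR13-contig15	386	339	4	5	1.28
MR1	513	+	1	contig1-MR1-contig2	contig43-MR1-contig44	contig1-MR1-contig44	contig43-MR1-contig2	429	333	9	11	2.50
MR2	794	-	1	contig19-MR2-contig20	contig28-MR2-contig27	contig19-MR2-contig27	contig28-MR2-contig20	450	352	19	18	4.05
MR3	553	-	1	contig11-MR3-contig12	contig36-MR3-contig35	contig11-MR3-contig35	contig36-MR3-contig12	443	390	118	55	21.03
MR4	574	-	1	contig16-MR4-contig17	contig35-MR4-contig34	contig16-MR4-contig34	contig35-MR4-contig17	379	448	14	14	3.03
MR5	858	+	1	contig13-MR5-contig14	contig46-MR5-contig47	contig13-MR5-contig47	contig46-MR5-contig14	433	323	26	64	12.88
MR6	911	-	1	contig15-MR6-contig16	contig45-MR6-contig44	contig15-MR6-contig44	contig45-MR6-contig16	352	370	8	11	2.89
LR1	1769	-	1	contig7-LR1-contig8	contig31-LR1-contig32	contig7-LR1-contig32	contig31-LR1-contig8	385	336	219	363	48.53
CR1	5692	+	1	contig6-CR1-contig10	contig26-CR1-contig27	contig6-CR1-contig27	contig26-CR1-contig10	90	72	88	74	49.44
CR2	19407	-	1	contig1-CR2-contig48	contig30-CR2-contig33	contig1-CR2-contig33	contig30-CR2-contig48	35	14	20	19	36.36
CR3	12002	?	0	contig6-CR3-contig48	contig26-CR3-contig33	contig6-CR3-contig33	contig26-CR3-contig48	30	35	32	25	47.76
CR4	13097	?	0	contig1-CR4-contig27	contig30-CR4-contig10	contig1-CR4-contig10	contig30-CR4-contig27	46	30	34	42	47.73
CR5	7561	-	1	contig28-CR5-contig30	contig40-CR5-contig38	contig28-CR5-contig38	contig40-CR5-contig30	120	123	113	145	45.90
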