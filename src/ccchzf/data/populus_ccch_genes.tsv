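gene	locus	at_ortholog	orf_bp	exons	length_aa	mol_wt_kd	pi	n_ccch_motifs
PtC3H1	POPTR_0007s01080.1	AT1G03790.1	1152	1	383	43.28	7.25	2
PtC3H2	POPTR_0017s04510.1	AT1G03790.1	1149	1	382	43.02	8.04	2
PtC3H3	POPTR_0002s21790.1	AT1G04990.1	1353	7	450	48.77	8.06	5
PtC3H4	POPTR_0014s15770.1	AT1G04990.1	1341	7	446	48.23	8.06	5
PtC3H5	POPTR_0009s04610.1	AT1G07360.1	1596	4	531	59.51	7.38	1
PtC3H6	POPTR_0009s04630.1	AT1G07360.1	1596	4	531	59.30	7.54	1
PtC3H7	POPTR_0004s23730.1	AT1G10320.1	780	4	259	31.16	4.73	1
PtC3H8	POPTR_0002s02670.1	AT1G19860.1	1278	4	425	46.16	6.38	1
PtC3H9	POPTR_0005s11800.1	AT1G19860.1	1722	5	573	63.08	8.47	1
PtC3H10	POPTR_0005s25760.1	AT1G19860.1	1263	5	420	45.18	7.05	1
PtC3H11	POPTR_0002s07810.1	AT1G21580.1	6363	10	2120	23.27	8.85	5
PtC3H12	POPTR_0005s20550.1	AT1G21580.1	6228	11	2075	22.86	8.33	5
PtC3H13	POPTR_0001s36810.1	AT1G30460.1	2010	9	669	73.34	6.90	3
PtC3H14	POPTR_0011s09220.1	AT1G30460.2	837	2	278	30.73	8.19	3
PtC3H15	POPTR_0001s02330.1	AT1G32360.1	1134	2	377	40.01	6.97	3
PtC3H16	POPTR_0003s09240.1	AT1G32360.1	1173	2	390	42.10	6.77	3
PtC3H17	POPTR_0004s09410.1	AT1G66810.1	942	1	313	34.79	8.04	2
PtC3H18	POPTR_0005s15100.1	AT1G66810.1	1017	2	338	37.23	8.22	2
PtC3H19	POPTR_0005s19930.1	AT1G66810.1	888	3	295	32.01	9.19	1
PtC3H20	POPTR_0010s12860.1	AT1G68200.2	801	3	266	30.20	8.28	2
PtC3H21	POPTR_0006s08100.1	AT1G75340.1	1299	11	432	46.50	8.66	1
PtC3H22	POPTR_0008s14320.1	AT2G02160.1	2229	3	742	81.56	5.41	3
PtC3H23	POPTR_0010s10850.1	AT2G02160.1	2208	3	735	81.12	5.59	3
PtC3H24	POPTR_0014s16340.1	AT2G05160.1	1731	8	576	65.58	6.87	1
PtC3H25	POPTR_0006s25080.1	AT2G19810.1	1173	1	390	42.62	7.86	2
PtC3H26	POPTR_0006s13510.1	AT2G20280.1	1116	8	371	42.43	5.49	2
PtC3H27	POPTR_0008s04540.1	AT2G20280.1	1092	8	363	41.12	5.06	2
PtC3H28	POPTR_0016s08500.1	AT2G20280.1	1083	8	360	41.15	5.06	2
PtC3H29	POPTR_0308s00200.1	AT2G20280.1	1077	8	358	40.76	5.48	2
PtC3H30	POPTR_0018s02840.1	AT2G24830.1	1536	4	511	56.91	4.83	1
PtC3H31	POPTR_0011s05550.1	AT2G33835.1	2010	5	669	73.52	7.52	1
PtC3H32	POPTR_0008s06940.1	AT2G40140.1	2040	1	679	73.87	7.68	2
PtC3H33	POPTR_0010s19520.1	AT2G40140.1	1839	4	612	66.62	6.77	2
PtC3H34	POPTR_0012s12760.1	AT2G40140.1	2025	1	655	71.58	7.01	2
PtC3H35	POPTR_0001s27370.1	AT2G41900.1	2133	1	710	77.59	6.94	2
PtC3H36	POPTR_0006s05240.1	AT2G41900.1	2208	1	735	79.81	6.40	2
PtC3H37	POPTR_0006s05250.1	AT2G41900.1	2106	1	701	76.47	6.36	2
PtC3H38	POPTR_0009s06580.1	AT2G41900.1	2187	1	728	79.28	6.50	2
PtC3H39	POPTR_0016s05410.1	AT2G41900.1	2199	1	732	79.67	6.50	2
PtC3H40	POPTR_0017s06030.1	AT2G47680.1	3171	13	1056	119.38	6.77	2
PtC3H41	POPTR_0013s08490.1	AT3G02830.1	1560	11	519	57.42	8.42	4
PtC3H42	POPTR_0013s08500.1	AT3G02830.1	318	2	105	11.16	7.34	1
PtC3H43	POPTR_0019s08030.1	AT3G02830.1	1338	7	445	48.48	8.51	5
PtC3H44	POPTR_0008s22730.1	AT3G06410.1	1434	7	477	50.53	8.62	5
PtC3H45	POPTR_0003s06730.1	AT3G08505.1	1548	10	515	59.51	9.26	2
PtC3H46	POPTR_0004s14200.1	AT3G08505.1	1395	6	464	52.58	7.66	4
PtC3H47	POPTR_0009s06730.1	AT3G08505.1	1155	8	384	42.48	8.10	4
PtC3H48	POPTR_0016s04690.1	AT3G12130.1	858	3	285	30.04	9.91	3
PtC3H49	POPTR_0008s07980.1	AT3G12680.1	1425	11	474	51.29	8.27	5
PtC3H50	POPTR_0010s18390.1	AT3G12680.1	1599	12	532	57.88	8.08	6
PtC3H51	POPTR_0005s06240.1	AT3G18640.1	2577	3	858	95.28	7.73	3
PtC3H52	POPTR_0007s03970.1	AT3G18640.1	2583	3	860	95.64	8.69	3
PtC3H53	POPTR_0003s06010.1	AT3G19360.1	795	2	264	28.80	9.99	3
PtC3H54	POPTR_0004s17670.1	AT3G19360.1	1155	2	384	42.89	8.48	3
PtC3H55	POPTR_0009s13310.1	AT3G19360.1	1026	2	341	38.08	7.94	3
PtC3H56	POPTR_0007s02620.1	AT3G21810.1	1314	11	437	49.05	9.09	1
PtC3H57	POPTR_0001s34600.1	AT3G27700.1	2946	5	981	107.01	6.94	1
PtC3H58	POPTR_0017s10830.1	AT3G27700.1	2961	5	986	107.25	7.20	1
PtC3H59	POPTR_0009s04950.1	AT3G47120.1	1053	4	350	41.27	8.97	1
PtC3H60	POPTR_0012s09400.1	AT3G48440.1	1434	6	477	53.20	5.48	5
PtC3H61	POPTR_0015s10050.1	AT3G48440.1	1494	7	497	56.30	5.13	5
PtC3H62	POPTR_0005s11920.1	AT3G51120.1	4575	11	1524	167.73	5.98	1
PtC3H63	POPTR_0004s16880.1	AT3G51120.1	3339	9	1112	121.35	7.18	1
PtC3H64	POPTR_0007s13760.1	AT3G51120.1	4818	10	1605	176.29	5.97	1
PtC3H65	POPTR_0007s13990.1	AT3G51180.1	1674	4	557	61.21	9.16	1
PtC3H66	POPTR_0001s05760.1	AT3G51950.1	2124	8	707	77.04	6.17	1
PtC3H67	POPTR_0001s26250.1	AT3G51950.1	1911	8	636	69.96	6.43	1
PtC3H68	POPTR_0003s20310.1	AT3G51950.1	2118	8	705	77.16	6.15	1
PtC3H69	POPTR_0009s05520.1	AT3G51950.1	2205	8	734	81.19	5.93	1
PtC3H70	POPTR_0012s13800.1	AT4G25440.1	1359	9	452	48.96	7.68	2
PtC3H71	POPTR_0015s13760.1	AT4G25440.1	1365	9	454	49.48	7.49	2
PtC3H72	POPTR_0018s04720.1	AT4G29190.1	1155	1	384	42.18	7.33	2
PtC3H73	POPTR_0009s12840.1	AT4G38890.1	2115	10	704	77.83	6.58	1
PtC3H74	POPTR_0001s05070.1	AT5G06770.1	915	3	304	32.51	9.80	3
PtC3H75	POPTR_0003s21780.1	AT5G06770.1	948	3	315	33.72	9.77	3
PtC3H76	POPTR_0006s20620.1	AT5G06770.1	1008	4	335	35.18	9.89	3
PtC3H77	POPTR_0016s04590.1	AT5G06770.1	855	3	284	29.92	9.79	3
PtC3H78	POPTR_0001s26240.1	AT5G12440.1	2025	7	674	74.81	5.72	1
PtC3H79	POPTR_0001s28300.1	AT5G12440.1	663	1	220	24.13	7.47	1
PtC3H80	POPTR_0007s12500.1	AT5G12440.1	291	1	96	10.76	8.22	1
PtC3H81	POPTR_0001s26560.1	AT5G12850.1	2028	1	675	73.98	6.76	2
PtC3H82	POPTR_0009s05810.1	AT5G12850.1	1887	1	628	69.16	6.72	2
PtC3H83	POPTR_0010s02320.1	AT5G18550.1	1371	7	456	48.77	8.53	5
PtC3H84	POPTR_0002s00480.1	AT5G42820.1	822	1	273	32.47	8.99	2
PtC3H85	POPTR_0004s20030.1	AT5G42820.1	963	5	320	37.42	9.61	2
PtC3H86	POPTR_0005s27940.1	AT5G42820.1	819	1	272	32.24	9.47	2
PtC3H87	POPTR_0006s11790.1	AT5G42820.1	936	4	311	36.25	9.40	2
PtC3H88	POPTR_0006s15670.1	AT5G56900.2	1821	9	606	67.52	6.90	2
PtC3H89	POPTR_0006s15080.1	AT5G56930.1	2787	7	928	101.34	8.46	3
PtC3H90	POPTR_0001s25960.1	AT5G58620.1	2115	1	704	76.38	6.14	2
PtC3H91	POPTR_0009s05150.1	AT5G58620.1	2067	1	703	74.40	5.97	2
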