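pair	gene1	gene2	ks	ka	ka_ks	duplication	structure_class	expression_code
1	PtC3H1	PtC3H2	0.3237	0.0906	0.2797	O	1	AA
2	PtC3H3	PtC3H4	0.2939	0.0477	0.1624	W	1	AA
3	PtC3H5	PtC3H6	0.0416	0.0088	0.2104	T	1	AA
4	PtC3H8	PtC3H10	0.2961	0.1455	0.4913	W	2	AB
5	PtC3H9	PtC3H65	0.3851	0.1906	0.4950	W	2	No
6	PtC3H11	PtC3H12	0.2979	0.1402	0.4706	W	2	AB
7	PtC3H13	PtC3H14	0.4247	0.1629	0.3835	W	2	No
8	PtC3H15	PtC3H16	0.3063	0.0483	0.1577	W	2	AC
9	PtC3H17	PtC3H18	0.3111	0.0603	0.1939	W	1	AC
10	PtC3H22	PtC3H23	0.2919	0.1136	0.3893	W	1	AB
11	PtC3H25	PtC3H72	0.3609	0.0571	0.1582	O	1	No
12	PtC3H26	PtC3H29	0.0125	0.0078	0.6247	O	2	No
13	PtC3H32	PtC3H34	0.1084	0.0482	0.4446	O	1	No
14	PtC3H35	PtC3H38	0.2903	0.0678	0.2334	W	1	AC
15	PtC3H36	PtC3H39	0.3407	0.0632	0.1855	W	1	No
16	PtC3H42	PtC3H43	0.3935	0.1055	0.2681	W	3	No
17	PtC3H44	PtC3H83	0.2825	0.0712	0.2521	O	1	AC
18	PtC3H46	PtC3H47	1.4585	0.7131	0.4889	O	2	AC
19	PtC3H48	PtC3H77	0.0234	0.0048	0.2064	T	1	No
20	PtC3H49	PtC3H50	0.2805	0.0684	0.2440	O	3	AB
21	PtC3H51	PtC3H52	0.2720	0.0812	0.2985	W	1	No
22	PtC3H54	PtC3H55	0.2172	0.0637	0.2930	W	2	No
23	PtC3H57	PtC3H58	0.1967	0.1130	0.5745	W	3	AA
24	PtC3H60	PtC3H61	0.2951	0.1372	0.4650	W	2	AB
25	PtC3H62	PtC3H64	0.2644	0.1031	0.3900	W	3	No
26	PtC3H66	PtC3H68	0.2405	0.0373	0.1552	W	1	AC
27	PtC3H67	PtC3H69	0.3284	0.1028	0.3131	O	1	No
28	PtC3H70	PtC3H71	0.2795	0.0818	0.2925	W	1	AB
29	PtC3H74	PtC3H75	0.2405	0.0364	0.1512	W	1	AB
30	PtC3H79	PtC3H80	0.2565	0.1364	0.5318	O	1	No
31	PtC3H81	PtC3H82	0.2465	0.1066	0.4326	W	1	AC
32	PtC3H84	PtC3H86	0.4725	0.0678	0.1435	W	1	AD
33	PtC3H85	PtC3H87	2.4099	0.1624	0.0674	O	2	AD
34	PtC3H90	PtC3H91	0.2513	0.0496	0.1972	W	1	AB
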