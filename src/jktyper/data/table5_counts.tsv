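allele	WEUR	TUR	SYR	SSAF	SEEA	SAS	CSAM	NAF	IRAQ	IRAN	EEKCA	ARPE	OTH	Total
JK1_total	540	2347	730	100	158	273	82	274	160	339	868	208	2282	8360
JK2_total	522	2213	682	40	156	203	74	180	174	317	830	182	2132	7706
JK*01	428	1721	561	48	49	149	54	184	120	253	685	155	1639	6034
JK*01W.01	2	14	1	0	0	1	0	0	1	1	7	0	5	32
JK*01W.03	0	0	0	0	0	0	0	0	0	0	0	0	1	1
JK*01W.04	0	0	0	0	0	0	0	0	0	0	0	0	1	1
JK*01W.06	7	19	7	9	0	1	6	9	0	4	4	2	29	97
JK*01N.09	0	0	0	0	0	0	0	0	0	0	3	0	0	3
JK*01N.18	0	1	0	0	0	0	0	0	0	0	1	0	0	2
JK*01N.20	3	35	15	9	0	0	0	19	5	1	8	4	35	134
JK*02	0	0	0	0	0	1	0	0	0	0	0	0	0	1
JK*02W.03	425	1832	561	37	91	171	68	162	139	260	689	157	1765	6357
JK*02N.17	0	0	0	0	0	0	0	0	0	0	0	0	1	1
JK*01W.01.588A_G	93	535	135	29	104	119	20	58	33	78	158	44	560	1966
JK*02N.17.588A_G	72	263	89	2	3	28	6	8	24	43	116	14	253	921
JK*02W.03.1095T_C	10	62	20	0	0	1	0	8	4	6	18	8	52	189
JK*02W.03.M167V	4	37	4	0	52	0	0	0	0	1	1	0	36	135
JK*02W.03.P90S	1	4	0	0	0	1	0	0	5	4	0	0	5	20
JK*02W.03.582C_T	6	0	1	0	2	0	0	1	0	0	1	0	5	16
JK*01.Q21R	1	2	2	0	0	0	0	0	0	0	1	0	2	8
JK*01.L148F	0	2	0	0	0	0	0	0	0	0	0	1	5	8
JK*01.E5-23G_A	0	2	2	0	0	0	0	1	1	0	0	0	2	8
JK*02W.04.588A_G	0	1	1	0	1	1	0	0	1	0	0	0	1	6
JK*01.1095T_C	0	5	1	0	0	0	0	0	0	0	0	0	0	6
JK*01W.02.402T_C_588A_G	2	0	0	2	0	0	0	0	0	0	0	0	2	6
JK*02W.03.L63F	0	1	2	0	0	0	0	0	0	0	0	0	2	5
JK*02N.01.588A_G	0	0	0	0	5	0	0	0	0	0	0	0	0	5
JK*02N.09.588A_G	0	2	0	0	0	0	0	0	0	0	1	0	2	6
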