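name	background	additional_changes	protein_changes	observations	phenotype_published	phenotype_revised	referenced	dbsnp	genbank	gnomad_maf	note
JK*01	-	-	-	5607	JK1	JK1	1			0.5792
JK*01N.09	JK*01	c.27_50del	V10_R17del	3	JK1_null	JK1_null	1	rs547922260		0.0014
JK*01N.18	JK*01	c.190C>T	R64W	2	JK1_null	JK1_null	1	rs552191196
JK*01N.20	JK*01	c.28G>A;c.226G>A;c.303G>A;c.588A>G	V10M;V76I;=;=	125	JK1_null	JK1	1	rs113578396;rs113029149;rs28994287;rs2298718		0.0179
JK*01W.01	JK*01	c.130G>A	E44K	30	JK1_weak	JK1_weak	1	rs2298720		0.1376
JK*01W.03	JK*01	c.28G>A	V10M	1	JK1_weak	JK1_weak	1	rs113578396		0.0179
JK*01W.04	JK*01	c.226G>A	V76I	1	JK1_weak	JK1_weak	1	rs113029149		0.022
JK*01W.06	JK*01	c.588A>G	=	87	JK1_weak	JK1	1	rs2298718		0.6124
JK*02	JK*01	c.838G>A	D280N	1	JK2	JK2	1	rs1058396		0.4208
JK*02W.03	JK*02	c.588A>G;c.838G>A	=;D280N	5941	JK2_weak	JK2	1	rs2298718;rs1058396		0.4208
JK*01.V8F	JK*01	c.22G>T	V8F	1			0		MW604784
JK*01.Q21R	JK*01	c.62A>G	Q21R	7		JK1	0	rs146079238		0.0003
JK*01.G27R	JK*01	c.79G>A	G27R	1			0		MW604779
JK*01.105T_C	JK*01	c.105T>C	=	2			0	rs1417111456
JK*01.159C_T	JK*01	c.159C>T	=	2			0	rs202168702		0.0001
JK*01.V54M	JK*01	c.160G>A	V54M	1			0	rs377124382
JK*01.163del	JK*01	c.163del	fs	1		JK1_null	0		MW604785
JK*01.R64Q	JK*01	c.191G>A	R64Q	1		JK1_null	0	rs114362217		0.0002	same missense as referenced null JK*02N.09
JK*01.V76A	JK*01	c.227T>C	V76A	1			0		MW712669
JK*01.V87I	JK*01	c.259G>A	V87I	1			0		MW604783
JK*01.G96V	JK*01	c.291G>T	G96V	1			0	rs2047018661
JK*01.L148F	JK*01	c.442C>T	L148F	6			0	rs563016158		0.0002
JK*01.L188F_561C_T	JK*01	c.561C>T;c.562C>T	=;L188F	1			0	rs778172038;rs200153291
JK*01.T308I	JK*01	c.923C>A	T308I	1			0	rs753184657
JK*01.T346M	JK*01	c.1037C>T	T346M	1			0	rs1377322159
JK*01.M352I	JK*01	c.1056G>A	M352I	4			0	rs1037329168
JK*01.L364F	JK*01	c.1090C>T	L364F	3			0		MW604780
JK*01.1095T_C	JK*01	c.1095T>C	=	6			0	rs28898897		0.0039
JK*01.V367A	JK*01	c.1100T>C	V367A	1			0		MW604782
JK*01.N373I	JK*01	c.1118A>T	N373I	1			0	rs35942326
JK*01.E4+10C_T	JK*01	c.341+10C>T	-	2			0		MW604801
JK*01.E5-19T_A	JK*01	c.342-19T>A	-	1			0	rs199975559		0.0001
JK*01.E5-23G_A	JK*01	c.342-23G>A	-	7			0	rs377318707		0.0001
JK*01.E5+12T_C	JK*01	c.470+12T>C	-	2			0	rs114641857		0.0029
JK*01.E8+31G_A	JK*01	c.946+31G>A	-	1			0	rs1473703649
JK*01.E9-13T_C	JK*01	c.947-13T>C	-	1			0		MW604802
JK*01.E9+18T_C	JK*01	c.996+18T>C	-	1			0	rs374156279		0.0001
JK*01N.09.V175I	JK*01N.09	c.523G>A	V175I	1		JK1_null	0	rs138222201		0.001	change printed as c.499G>A; corrected to c.523G>A via rs138222201 cross-reference
JK*01W.01.D11N_588A_G	JK*01W.01	c.31G>A;c.588A>G	D11N;=	3			0	rs1307492731;rs2298718
JK*01W.01.219C_T_588A_G	JK*01W.01	c.219C>T;c.588A>G	=;=	1			0	rs779835840;rs2298718
JK*01W.01.279C_T_588A_G	JK*01W.01	c.279T>C;c.588A>G	=;=	1			0	rs1391927371;rs2298718			printed token 279C_T swaps ref/alt of the printed change c.279T>C; name kept as printed
JK*01W.01.T127I_588A_G	JK*01W.01	c.380C>T;c.588A>G	T127I;=	1			0	rs2298718	MW604786
JK*01W.01.516C_T_588A_G	JK*01W.01	c.516C>T;c.588A>G	=;=	2			0	rs747405896;rs2298718
JK*01W.01.588A_G	JK*01W.01	c.588A>G	=	1820	JK1_weak	JK1_weak	0	rs2298718		0.1376
JK*01W.01.588A_G_E9-7T_G	JK*01W.01	c.588A>G;c.812-7T>C	=;-	1			0	rs2298718;rs567213799			printed intron token E9-7T_G; anchor rule places c.812-7 in intron 7 (E8-7T_C); name kept as printed
JK*01W.01.F329V_588A_G	JK*01W.01	c.588A>G;c.985T>G	=;F329V	1			0	rs2298718;rs767190566
JK*01W.01.P205S_588A_G	JK*01W.01	c.613C>T;c.588A>G	P205S;=	1			0	rs760632131;rs2298718
JK*01W.02.402T_C_588A_G	JK*01W.02	c.402T>C;c.588A>G	=;=	6			0	rs16978473;rs2298718		0.0041
JK*01W.02.402T_C_588A_G_E5-24C_T	JK*01W.02	c.402T>C;c.588A>G;c.342-24C>T	=;=;-	1			0	rs16978473;rs2298718;rs202136116
JK*01W.04.303G_A	JK*01W.04	c.303G>A	=	4		JK1_weak	0	rs28994287		0.0218
JK*01W.06.V54M	JK*01W.06	c.160G>A	V54M	2			0	rs377124382
JK*01W.06.M167V	JK*01W.06	c.499A>G	M167V	3		JK1	0	rs2298719		0.0082
JK*02N.01.588A_G	JK*02N.01	c.588A>G	=	5	JK2_null	JK2_null	0	rs78937798;rs2298718		0.0005
JK*02N.05.588A_G	JK*02N.05	c.588A>G	=	1	JK2_null	JK2_null	0	rs2298718;rs759505281
JK*02N.06.588A_G	JK*02N.06	c.588A>G	=	1	JK2_null	JK2_null	0	rs2298718;rs78242949		0.0018
JK*02N.08.588A_G	JK*02N.08	c.588A>G	=	2	JK2_null	JK2_null	0	rs2298718;rs565898944		0.0002
JK*02N.09.588A_G	JK*02N.09	c.588A>G	=	5	JK2_null	JK2_null	0	rs114362217;rs2298718		0.0002
JK*02N.09.210G_A_588A_G	JK*02N.09	c.210G>A;c.588A>G	=;=	1		JK2_null	0	rs1796634758;rs2298718
JK*02N.17.588A_G	JK*02N.17	c.588A>G	=	859	JK2_null	JK2	0	rs2298718		0.0456
JK*02N.17.588A_G_957G_A	JK*02N.17	c.588A>G;c.957G>A	=;=	1			0	rs2298718;rs376375507
JK*02N.17.588A_G_1095T_C	JK*02N.17	c.588A>G;c.1095T>C	=;=	1		JK2	0	rs2298718;rs28898897		0.0039
JK*02W.03.M7V	JK*02W.03	c.19A>G	M7V	1			0	rs138369087
JK*02W.03.V10M_V76I_303G_A	JK*02W.03	c.28G>A;c.226G>A;c.303G>A	V10M;V76I;=	4		JK2	0	rs113578396;rs113029149;rs28994287		0.0179
JK*02W.03.56insA_549G_A	JK*02W.03	c.56insA;c.549G>A	fs;=	1		JK2_null	0	rs375370757	MW604799	0.0001	name printed 56irsA in the table, 56insA in the running text
JK*02W.03.69G_A	JK*02W.03	c.69G>A	=	1			0	rs140137213		0.0002
JK*02W.03.Y37X	JK*02W.03	c.111T>G	Y37X	1		JK2_null	0		MW604800
JK*02W.03.L63F	JK*02W.03	c.187C>T	L63F	5			0	rs201716471		0.0001
JK*02W.03.V76I	JK*02W.03	c.226G>A	V76I	1		JK2	0	rs113029149		0.022
JK*02W.03.P90S	JK*02W.03	c.268C>T	P90S	18		JK2	0	rs147790844
JK*02W.03.T95I_V175I	JK*02W.03	c.284C>T;c.523G>A	T95I;V175I	1			0	rs764618306;rs138222201
JK*02W.03.D113E	JK*02W.03	c.339C>G	D113E	1			0		MW604791
JK*02W.03.W144R	JK*02W.03	c.430T>C	W144R	1			0		MW604798
JK*02W.03.M167V	JK*02W.03	c.499A>G	M167V	127		JK2	0	rs2298719		0.0082
JK*02W.03.582C_T	JK*02W.03	c.582C>T	=	15		JK2	0	rs34756616		0.0035
JK*02W.03.591C_T	JK*02W.03	c.591C>T	=	1			0	rs748824511			table rendering of the name is garbled; token rebuilt from the printed change c.591C>T
JK*02W.03.N211S	JK*02W.03	c.632A>G	N211S	1			0		MW604795	table rendering of the name is garbled; token rebuilt from the printed change p.Asn211Ser
JK*02W.03.667C_T	JK*02W.03	c.667C>T	=	1			0	rs748771470
JK*02W.03.678A_T	JK*02W.03	c.678A>T	=	1			0		MW604788
JK*02W.03.840C_T	JK*02W.03	c.840C>T	=	3			0		MW604789
JK*02W.03.948C_G	JK*02W.03	c.948C>G	=	1			0		MW604790
JK*02W.03.957G_A	JK*02W.03	c.957G>A	=	2			0	rs376375507
JK*02W.03.L322F	JK*02W.03	c.964C>T	L322F	1			0		MW604794
JK*02W.03.G325S	JK*02W.03	c.973G>A	G325S	1		JK2	0	rs140320419		0.0001
JK*02W.03.1047C_T	JK*02W.03	c.1047C>T	=	1			0		MW604787
JK*02W.03.K355N_E9+9G_T	JK*02W.03	c.1065A>G;c.996+9G>T	K355N;-	1			0	rs188063122	MW604793
JK*02W.03.P363H	JK*02W.03	c.1088C>A	P363H	1			0		MW604796
JK*02W.03.1095T_C	JK*02W.03	c.1095T>C	=	176		JK2	0	rs28898897		0.0039
JK*02W.03.E371K	JK*02W.03	c.1111G>A	E371K	2			0	rs756254780
JK*02W.03.F376L	JK*02W.03	c.1126T>C	F376L	1			0	rs772420027
JK*02W.03.I375V	JK*02W.03	c.1123A>G	I375V	1			0		MW604792
JK*02W.03.V385M	JK*02W.03	c.1153G>A	V385M	1			0		MW604797
JK*02W.03.E8-38C_G	JK*02W.03	c.812-38C>G	-	1			0	rs369987138
JK*02W.03.E9+9G_T	JK*02W.03	c.996+9G>T	-	1			0	rs188063122		0.0004
JK*02W.04.588A_G	JK*02W.04	c.588A>G	=	6	JK2_weak	JK2_weak	0	rs2298720;rs2298718		0.1376
JK*02W.04.M167V_588A_G	JK*02W.04	c.499A>G;c.588A>G	M167V;=	3		JK2_weak	0	rs2298719;rs2298718		0.0082
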