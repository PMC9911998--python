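name	background	additional_changes	protein_changes	observations	het_jk12	hom_n	phenotype_published	phenotype_revised	referenced	presumed_phenotype	serotype	intensity	dbsnp	gnomad_maf	printed_exon
JK*01	-	-	-	433	208	80	JK1	JK1	1	JK:1	JK:1	3-4
JK*01N.20	JK*01	c.28G>A;c.226G>A;c.303G>A;c.588A>G	V10M;V76I;=;=	9	1	1	JK1_null	JK1	1	JK:Null	JK:1	n.d.	rs113578396;rs113029149;rs28994287;rs2298718	0.0179	Exon 3;Exon 4;Exon 4;Exon 6
JK*01W.01	JK*01	c.130G>A	E44K	2	0	0	JK1_weak	JK1_weak	1	JK:1weak	-	not_possible	rs2298720	0.1376	Exon 3
JK*01W.06	JK*01	c.588A>G	=	11	4	1	JK1_weak	JK1	1	JK:1weak	JK:1	4	rs2298718	0.6124	Exon 6
JK*02N.17	JK*02	c.810G>A	=	1	1	0	JK2_null	JK2	1	JK:Null	JK:2	n.d.	rs17675299	0.0456	Exon 7
JK*02W.03	JK*02	c.588A>G	=	413	229	77	JK2_weak	JK2	1	JK:2weak	JK:2	3-4	rs2298718	0.4208	Exon 6
JK*01.Q21R	JK*01	c.62A>G	Q21R	1	1	0	unknown	JK1	0	Unknown	JK:1	4	rs146079238	0.0003	Exon 3
JK*01.L148F	JK*01	c.442C>T	L148F	2	0	0	unknown	unknown	0	Unknown	-	not_possible	rs563016158	0.0002	Exon 4
JK*01W.01.588A_G	JK*01W.01	c.588A>G	=	147	63	16	JK1_weak	JK1_weak	0	JK:1weak	JK:1weak	2-4	rs2298718	0.6124	Exon 6
JK*02N.01.588A_G	JK*02N.01	c.588A>G	=	1	1	0	JK2_null	JK2_null	0	JK:Null	JK:2-	0	rs78937798;rs2298718	0.0005	Intron 4;Exon 6
JK*02N.17.588A_G	JK*02N.17	c.588A>G	=	56	31	2	JK2_null	JK2	0	JK:Null	JK:2	4	rs2298718	0.6124	Exon 6
JK*02W.03.P90S	JK*02W.03	c.268C>T	P90S	2	1	0	unknown	JK2	0	Unknown	JK:2	4	rs147790844	0.0001	Exon 4
JK*02W.03.M167V	JK*02W.03	c.499A>G	M167V	9	4	1	unknown	JK2	0	Unknown	JK:2	3-4	rs2298719	0.0082	Exon 6
JK*02W.03.582C_T	JK*02W.03	c.582C>T	=	1	1	0	unknown	JK2	0	Unknown	JK:2	n.d.	rs34756616	0.0035	Exon 6
JK*02W.03.1095T_C	JK*02W.03	c.1095T>C	=	13	8	0	unknown	JK2	0	Unknown	JK:2	4	rs28898897	0.0039	Exon 10
JK*02W.03.G325S	JK*02W.03	c.973G>A	G325S	1	1	0	unknown	JK2	0	Unknown	JK:2	n.d.	rs140320419	0.0001	Exon 9
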