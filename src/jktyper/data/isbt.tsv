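name	background	additional_changes	protein_changes	phenotype_published	phenotype_revised	referenced	dbsnp	gnomad_maf	genbank
JK*01	-	-	-	JK1	JK1	1
JK*02	JK*01	c.838G>A	D280N	JK2	JK2	1	rs1058396	0.4208
JK*01W.01	JK*01	c.130G>A	E44K	JK1_weak	JK1_weak	1	rs2298720	0.1376
JK*01W.02	JK*01	c.511T>C	W171R	JK1_weak	JK1_weak	1	rs9948825
JK*01W.03	JK*01	c.28G>A	V10M	JK1_weak	JK1_weak	1	rs113578396	0.0179
JK*01W.04	JK*01	c.226G>A	V76I	JK1_weak	JK1_weak	1	rs113029149	0.022
JK*01W.06	JK*01	c.588A>G	=	JK1_weak	JK1	1	rs2298718	0.6124
JK*01N.09	JK*01	c.27_50del	V10_R17del	JK1_null	JK1_null	1	rs547922260	0.0014
JK*01N.18	JK*01	c.190C>T	R64W	JK1_null	JK1_null	1	rs552191196
JK*01N.20	JK*01	c.28G>A;c.226G>A;c.303G>A;c.588A>G	V10M;V76I;=;=	JK1_null	JK1	1	rs113578396;rs113029149;rs28994287;rs2298718	0.0179
JK*02W.03	JK*02	c.588A>G	=	JK2_weak	JK2	1	rs2298718	0.4208
JK*02W.04	JK*02	c.130G>A	E44K	JK2_weak	JK2_weak	1	rs2298720
JK*02N.01	JK*02	c.342-1G>A	splice	JK2_null	JK2_null	1	rs78937798	0.0005
JK*02N.05	JK*02	c.723del	fs	JK2_null	JK2_null	1	rs759505281
JK*02N.06	JK*02	c.871T>C	S291P	JK2_null	JK2_null	1	rs78242949
JK*02N.08	JK*02	c.956C>T	T319M	JK2_null	JK2_null	1	rs565898944
JK*02N.09	JK*02	c.191G>A	R64Q	JK2_null	JK2_null	1	rs114362217	0.0002
JK*02N.17	JK*02	c.810G>A	=	JK2_null	JK2	1	rs17675299	0.0456
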