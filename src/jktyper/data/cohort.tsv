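panel	validation	prospective	no_calls	genotyped
OTH	182	2036	10	2207
TUR	140	2148	8	2280
EEKCA	63	788	2	849
SYR	48	661	3	706
IRAN	24	305	1	328
SAS	12	226	0	238
NAF	14	215	2	227
ARPE	16	180	1	195
IRAQ	14	153	0	167
SEEA	13	144	0	157
CSAM	4	74	0	78
SSAF	14	56	0	70
WEUR	7	528	3	531
Total	551	7512	30	8033
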