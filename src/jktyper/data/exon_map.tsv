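exon	cds_start	cds_end	source_tag
3	1	144	synthetic
4	145	341	synthetic
5	342	470	synthetic
6	471	654	synthetic
7	655	811	synthetic
8	812	946	synthetic
9	947	996	synthetic
10	997	1170	synthetic
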