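ID	SSR nr.	type	SSR	size	start	end	aln_start	aln_end	at_edge	truncated
SA1a|L2	1	p4	(GCAT)3	12	97	108	98	109	0	0
SA1a|L4	1	p3	(TGC)4	12	250	261	250	261	0	0
SA1a|L7	1	p4	(TTTG)4	16	46	61	121	136	0	0
SA1b|L2	1	p4	(GCAT)3	12	97	108	98	109	0	0
SA1b|L5	1	p2	(AC)8	16	188	203	257	272	0	0
SA1b|L7	1	p4	(TTTG)3	12	1	12	125	136	1	1
SA2|L1	1	p2	(AG)7	14	40	53	162	175	0	0
SA2|L3	1	p2	(AG)6	12	127	138	192	203	0	0
SA2|L4	1	p3	(TGC)6	18	249	266	250	267	0	0
SB1|L3	1	p2	(AG)6	12	191	202	192	203	0	0
SB1|L6	1	c	(GTAT)3(GT)12	36	158	193	159	194	0	0
SB2|L5	1	p2	(AC)11	22	257	278	257	278	0	0
SB2|L6	1	c	(GTAT)3(GT)12	36	159	194	159	194	0	0
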