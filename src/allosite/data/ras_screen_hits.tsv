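compound_id	dataset	pocket	nOHNH	nON	logp	mw
16195481	PubChem Bioassay	p3	4	8	1.626	420.52
5446021	PubChem Bioassay	p3	3	7	2.567	397.46
5446018	PubChem Bioassay	p3	3	7	1.882	397.46
5295758	PubChem Bioassay	p3	1	6	3.57	415.56
4121863	PubChem Bioassay	p3	3	5	4.83	392.53
3227807	PubChem Bioassay	p3	1	8	3.737	447.52
12971189	Zinc drugs-now subset	p3	3	6	0.515	228.26
16958504	Zinc drugs-now subset	p3	4	9	-3.901	305.32
17047255	Zinc drugs-now subset	p3	7	6	-0.524	279.33
19166944	Zinc drugs-now subset	p3	1	5	-1.04	312.37
24983237	Zinc drugs-now subset	p3	4	9	-4.469	335.37
6682086	Zinc drugs-now subset	p3	3	5	-0.247	300.38
6691859	Zinc drugs-now subset	p3	7	6	-3.477	185.26
13616	NCIDS II	p3	2	4	4.317	327.46
23895	NCIDS II	p3	2	4	2.857	221.25
36818	NCIDS II	p3	2	8	1.602	374.48
99660	NCIDS II	p3	1	6	1.105	339.48
117028	NCIDS II	p3	1	4	4.06	398.30
121182	NCIDS II	p3	6	9	-2.303	266.26
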