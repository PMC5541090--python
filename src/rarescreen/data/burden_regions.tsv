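sample_count	n_variants	chrom	start	end	gene	region	sample_ids
7	1	19	535931	536148	CDC34	UPSTREAM	Y482,Y375,Y393,Y426,Y532,Y787,Y919
6	1	5	111091613	111091736	NREP	SPLICE	BIB82,Y316,Y331,Y482,Y516,Y558
6	4	2	242666998	242668839	ING5	3' UTR	Y166,Y292,Y591,Y724,Y988,Y787
5	4	11	117156433	117160295	BACE1	3' UTR	BrA206,Y331,Y645,Y919,Y292
5	2	22	23505688	23506663	RAB36	3' UTR	Br333,Y331,Br857,Y166,Y558
5	5	1	118507671	118509205	SPAG17	3' UTR	Y375,Y393,Y421,Y520,Y532
5	5	2	240504919	240507676	ENST00000358775	3' UTR	BIB82,Y375,Y426,Y532,Y724
4	4	X	17750592	17754159	NHS	3' UTR	Y426,Y516,Y532,Y919
4	1	15	20875075	20875135	NBEAP1	INTRON	BIB82,BrA206,Y724,Y919
4	1	5	147649533	147649718	SPINK13	INTRON	Y331,Y393,Y532,Y591
4	1	20	2732322	2732689	EBF4	UPSTREAM	BIB82,Y393,Y516,Y558
4	2	3	130282083	130282518	COL6A6	EXONIC	Y166,Y292,Y724,Y482
4	2	12	42475627	42481688	GXYLT1	3' UTR	Y166,Y591,Y919,Y787
4	3	2	210884434	210885839	RPE	3' UTR	Br857,Y919,Y558,Y591
4	3	7	139246399	139257490	HIPK2	3' UTR	Y166,Y787,Y292,Y516
4	3	9	87486857	87492822	NTRK2	3' UTR	Br333,Y375,Y426,Y645
4	4	18	11852188	11853806	GNAL	3' UTR	Br857,Y292,Y421,Y787
4	4	1	3350379	3355244	PRDM16	3' UTR	Y292,Y421,Y426,Y988
4	4	7	141356464	141362505	KIAA1147	3' UTR	Br333,Y292,Y375,Y645
4	4	4	164445811	164449937	MARCH1	3' UTR	Y166,Y516,Y532,Y988
4	4	15	67482895	67487583	SMAD3	3' UTR	Br857,BrA206,Y421,Y532
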