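gene	chrom	pos	ref	alt	consequence	sample_ids
MRPL45	17	36478478	A	C	stop-loss	BrA206,Y426
CACNA2D4	12	2024019	C	A	splice donor & intron	Y516
OTOGL	12	80764471	T	C	splice donor & intron	Y591
CWC27	5	64084836	C	T	stop-gain	Y520
SPATA31C2	9	90748568	T	A	splice acceptor & intron	Y558
RGL4	22	24041028	CAGCTACAAGCTGT	C	splice acceptor & splice region & intron & non-coding transcript exon	Y331
PMCH	12	102591506	AAGTT	A	frameshift	Y532
TRIM15	6	30131613	C	GC	frameshift	Br333
CEP85L	6	118880200	T	G	stop-gain	Y166
NME1	17	49231585	G	C	splice acceptor & intron	Y166
ZNF718	4	60294	T	C	stop-loss & splice region	Y375
CENPC	4	68385221	C	G	splice acceptor & intron	Y724
CDK14	7	90338857	T	C	start-loss	Y591
RAB3GAP2	1	220363490	T	C	splice acceptor & intron	Y292
PMM2	16	8900171	A	G	splice acceptor & intron	Y375
TMPRSS11F	4	68919659	G	A	stop-gain	Y919
SURF4	9	136233553	T	A	splice acceptor & intron	Y482
CKB	14	103988441	G	A	stop-gain	Y919
PCYOX1L	5	148742545	CAA	C	frameshift	Y532
MIXL1	1	226413300	T	A	stop-gain	Y516
D2HGDH	2	242688420	C	CCTGTGAGGATGGTC	splice donor & splice region & intron	Y724
PSKH1	16	67961717	C	T	splice acceptor & intron	Y316
BRMS1L	14	36333074	A	G	splice acceptor & intron	Y919
ST14	11	130058476	AT	A	frameshift	Y591
STRA8	7	134925307	CA	C	frameshift	Y919
ARRDC2	19	18120687	C	T	stop-gain	Y292
BOD1L1	4	13629016	GC	G	frameshift	Y292
H2AFZ	4	100871387	T	C	splice donor & intron	Y426
CFAP70	10	75056798	A	G	splice donor & intron	Y166
SKOR2	18	44746383	T	C	splice acceptor & intron	Y558
PRKAG2	7	151573704	A	G	start-loss	Y316
ADRA1A	8	26636945	C	A	stop-gain & splice region	Y516
TMEM132C	12	129189800	G	T	stop gain	Y421
S100A13	1	153600595	A	AC	splice donor & intron	Y724
DLG2	11	83191415	G	A	stop-gain & splice region	Y331
PCSK5	9	78790138	A	AATGGAATGGAATGAAATGGAATGGAATGGAATGGA	frameshift	Y421
C1orf226	1	162353052	CCA	C	frameshift	Y426
EPS15	1	51946947	GTC	G	frameshift	Y482
WDR12	2	203749260	T	C	splice acceptor & intron	Y375
TMA16	4	164415989	G	A	splice donor & intron	Y645
LOC100507443	2	208993176	C	CA	frameshift	Y516
CES4A	16	67035297	TC	T	frameshift	Y558
NUDCD3	7	44530037	G	GCT	frameshift	Y724
TP53RK	20	45315393	T	C	stop-loss	Y331
RABGGTA	14	24737761	C	T	stop-gain	Y919
UBE2E3	2	181846846	AC	A	frameshift	Y166
MPDZ	9	13140066	A	G	start-loss	Br857
TNFRSF11B	8	119936822	G	A	stop-gain	Y919
ABI1	10	27054244	TC	T	frameshift & splice region	Y919
HAPLN1	5	82940440	TGA	T	frameshift	BrA206
MRAP2	6	84772679	C	CT	frameshift	Y591
CAND2	3	12854548	G	T	stop-gain	Y393
CACNA1C	12	2659708	A	C	splice acceptor & intron	Y988
KRTAP2-4	17	39221826	G	GA	frameshift	BrA206
SORL1	11	121502724	G	C	splice acceptor & intron	Y520
LRRC37A4P	17	43585907	T	C	splice acceptor & intron	Y482
PEMT	17	17409148	T	G	stop-loss	Y645
RBMXL2	11	7110854	GC	G	frameshift	Br333
ZNF646	16	31091705	C	T	stop-gain	Br857
RBM12B	8	94752787	T	A	stop-loss	Y787
TGIF2LY	Y	3447816	GCC	G	frameshift	Y645
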