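gene	chrom	pos	ref	alt	consequence	sample_ids
RP2	X	46696585	C	T	missense variant	Y558
RP2	X	46696543	G	C	missense variant	Y591
LINC00632	X	139795826	G	A	missense variant	Y645
TSPAN6	X	99890198	C	T	missense variant	BrA206
PBDC1	X	75397790	A	C	missense variant	Y482
NR0B1	X	30326933	C	A	missense variant	Y482
TIMP1	X	47444635	C	G	missense variant	BIB82
TFE3	X	48888013	C	T	missense variant	BrA206
TAB3	X	30864180	A	G	missense variant	Y591
CXorf23	X	19948685	G	A	missense variant	Y558
MAMLD1	X	149681090	A	C	missense variant	Y591
STARD8	X	67937097	A	G	missense variant	Y919
RBM10	X	47006890	G	A	missense variant	Y919
MAP3K15	X	19398252	C	T	missense variant	Y645
ALG13	X	111003183	G	A	missense variant	Y787
ATP11C	X	138884497	G	A	missense variant & splice region variant	Y166
TRO	X	54956296	G	A	missense variant	Y482
AFF2	X	148037417	G	T	missense variant	BIB82
DMD	X	31366742	C	T	missense variant	Y482
OPHN1	X	67273643	T	C	missense variant	BrA206
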