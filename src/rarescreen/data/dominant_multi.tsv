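gene	sample_count
DOT1L	4
TTC28	4
TTC34	3
SCLY	3
SPHKAP	3
SOGA1	3
YES1	3
OTOG	2
PIK3R4	2
SHISA6	2
ZBTB49	2
TATDN2	2
DEDD2	2
MAP3K14-AS1	2
SMARCC1	2
TXLNA	2
DGKA	2
C1QTNF7	2
ZFC3H1	2
BIK	2
STC2	2
GMEB2	2
KLF7	2
APLP2	2
DCC	2
TNS1	2
PER2	2
MIXL1	2
KIAA1429	2
MCAM	2
LAMA3	2
MNX1	2
PRSS56	2
KIAA1549	2
SBF1	2
MRPL45	2
MYBPC1	2
PHF20	2
VAC14	2
RPH3A	2
NINJ1	2
REST	2
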