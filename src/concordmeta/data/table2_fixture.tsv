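gene	direction	all	human	sn
HSPA1A	up	4	3	3
RELN	up	4	4	3
PTPRC	up	3	2	0
LCN2	up	3	0	0
PLIN4	up	3	0	0
MAFF	up	3	2	2
SLCO4A1	up	3	3	2
HSPA1B	up	3	3	3
IGF2BP2	up	3	0	0
CDKN1A	up	3	0	0
ENC1	up	3	2	1
EGR2	down	6	0	0
FOS	down	5	2	1
RGS4	down	5	5	3
TAC1	down	5	4	3
SLC6A3	down	4	3	3
AGTR1	down	4	4	3
FGF13	down	4	3	4
PCSK1	down	4	3	2
NPTX2	down	4	1	1
GABBR2	down	4	3	2
NR4A2	down	4	3	4
EIF1AY	down	3	2	2
SATB2	down	3	0	0
RET	down	3	1	2
SNCA	down	3	3	0
TTR	down	3	0	0
CCK	down	3	0	0
DDC	down	3	3	3
SLC18A2	down	3	3	3
ALDH1A1	down	3	3	3
KCNJ6	down	3	2	2
TMEM255A	down	3	3	3
SCG2	down	3	3	3
GPR26	down	3	2	3
DCLK1	down	3	2	0
DUSP1	down	3	2	1
HPCAL4	down	3	2	1
SYNGR3	down	3	3	2
PREPL	down	3	3	0
STMN2	down	3	3	2
VSNL1	down	3	3	2
NTS	down	3	2	3
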