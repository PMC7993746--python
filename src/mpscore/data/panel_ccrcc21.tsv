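symbol	score_high	score_low	weight
DDAH1	1	0	3.580
CRABP2	0	1	3.009
TGFA	1	0	3.425
SEMA3G	1	0	3.042
SPATA18	1	0	4.169
PTTG1	0	1	3.344
SCGN	1	0	4.200
CYP39A1	1	0	3.595
CLDN4	1	0	3.541
ZNF395	1	0	3.977
IL15RA	0	1	3.859
APLNR	1	0	3.072
APOLD1	1	0	3.207
NTN4	1	0	3.723
PABPC1L	0	1	3.670
UBE2C	0	1	4.217
CDH4	1	0	3.183
GNG7	1	0	3.515
CEACAM1	1	0	3.506
PLAUR	0	1	3.418
SIM2	0	1	3.364
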