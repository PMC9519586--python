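# Candidate pathogenic variant counts per gene and cumulative evidence tier,
# as reported for the 8.3KJPN whole-genome reference panel screen
# (8380 Japanese individuals; 32 recessive DSD/CHG genes).
gene	set1	set2	set3	set4
CBX2	0	2	2	2
DHH	0	0	0	0
RSPO1	0	0	0	0
TSPYL1	0	0	0	0
WNT4	0	1	1	1
CYP11B1	0	1	1	1
CYP17A1	1	1	5	6
HSD3B2	0	1	2	5
STAR	4	4	4	5
CYP21A2	0	0	1	2
AMH	0	0	0	5
AMHR2	0	0	0	3
CYP19A1	0	3	3	5
HSD17B3	2	8	8	9
LHCGR	0	1	1	1
SRD5A2	0	0	6	8
AKR1C4	0	0	0	0
AKR1C2	0	0	0	0
POR	3	6	7	10
CYP11A1	0	1	1	1
CYB5A	0	0	0	0
HSD17B4	0	1	1	3
DHCR7	0	2	3	9
AR	0	0	0	3
GNRHR	1	3	4	4
GNRH1	0	0	0	0
TAC3	0	0	0	0
LEP	1	1	1	1
PROP1	1	1	1	1
LHX3	1	1	1	1
FSHR	0	0	0	1
BBS9	0	4	4	4
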