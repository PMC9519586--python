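gene	category	inheritance	chrom	start	end	mim	phenotype_mim
CBX2	GD	autosomal_recessive	chr17	77740000	77780000	602770	613080
DHH	GD	autosomal_recessive	chr12	49480000	49530000	605423	233420
TSPYL1	GD	autosomal_recessive	chr6	116590000	116630000	604714	608800
RSPO1	GD	autosomal_recessive	chr1	38070000	38110000	609595	610644
WNT4	GD	autosomal_recessive	chr1	22440000	22480000	603490	611812
CYP11B1	HSA	autosomal_recessive	chr8	143950000	143990000	610613	202010
HSD3B2	HSA	autosomal_recessive	chr1	119950000	119990000	613890	201810
CYP21A2	HSA	autosomal_recessive	chr6	32000000	32040000	613815	201910
STAR	HSA	autosomal_recessive	chr8	38000000	38040000	600617	201710
CYP17A1	HSA	autosomal_recessive	chr10	104580000	104620000	609300	202110
CYP11A1	HSA	autosomal_recessive	chr15	74630000	74670000	118485	613743
AMH	HSA	autosomal_recessive	chr19	2240000	2280000	600957	261550
AMHR2	HSA	autosomal_recessive	chr12	53810000	53850000	600956	261550
CYP19A1	HSA	autosomal_recessive	chr15	51500000	51630000	107910	613546
HSD17B3	HSA	autosomal_recessive	chr9	99000000	99060000	605573	264300
LHCGR	HSA	autosomal_recessive	chr2	48910000	48980000	152790	238320
SRD5A2	HSA	autosomal_recessive	chr2	31740000	31800000	607306	264600
AKR1C4	HSA	autosomal_recessive	chr10	5230000	5260000	600451	614279
AKR1C2	HSA	autosomal_recessive	chr10	5040000	5070000	600450	614279
POR	HSA	autosomal_recessive	chr7	75540000	75620000	124015	201750
CYB5A	HSA	autosomal_recessive	chr18	71980000	72020000	613218	250790
HSD17B4	HSA	autosomal_recessive	chr5	118780000	118880000	601860	233400
DHCR7	HSA	autosomal_recessive	chr11	71140000	71180000	602858	270400
AR	HSA	x_linked_recessive	chrX	66760000	66950000	313700	300068/300633
GNRHR	CHG	autosomal_recessive	chr4	68600000	68640000	138850	146110
GNRH1	CHG	autosomal_recessive	chr8	25270000	25300000	152760	614841
TAC3	CHG	autosomal_recessive	chr12	57390000	57420000	162330	614839
LEP	CHG	autosomal_recessive	chr7	127880000	127900000	164160	614962
PROP1	CHG	autosomal_recessive	chr5	177410000	177430000	601538	262600
LHX3	CHG	autosomal_recessive	chr9	139080000	139100000	600577	221750
FSHR	CHG	autosomal_recessive	chr2	49180000	49380000	136435	233300
BBS9	CHG	autosomal_recessive	chr7	33160000	33650000	607968	615986
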