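gene	transcript	ratio_denominator	ratio_numerator	fc_printed	sites_5utr	sites_cds	sites_3utr	growth_go
DYNLRB1	ENST00000357156	1.0	6.4	6.4
VPS18	ENST00000220509	8.5	43.4	5.1
NAPA-AS1	ENST00000594367	1.2	5.2	4.3			7mA1
C11orf95	ENST00000433688	1.0	4.2	4.2
HOMEZ	ENST00000357460	1.2	4.3	3.5
TMEM79	ENST00000405535	1.7	5.7	3.4
FOXP1	ENST00000493089	4.5	14.9	3.3		7m8/8m		yes
PCIF1	ENST00000372409	1.0	3.2	3.2		7m8
ATP6V0C	ENST00000330398	1.0	3.1	3.1
CISH	ENST00000348721	2.1	6.6	3.1			8m	yes
lnc-FOXB1-8	lnc-FOXB1-8:1	1.0	3.3	3.1
MT1B	ENST00000334346	1.1	3.5	3.1				yes
lnc-EGLN1-1	lnc-EGLN1-1:6	1.0	2.9	2.9
NELFA	ENST00000382882	1.0	3.0	2.9
BCR	ENST00000305877	1.0	2.8	2.8		7m8	7m8	yes
MT1L	ENST00000565768	1.2	3.2	2.8
FAT3	ENST00000409404	1.0	2.7	2.7		8m	7mA1
TRAF3IP2-AS1	ENST00000525151	1.0	2.7	2.7
C22orf39	ENST00000611555	1.0	2.6	2.6
KRTCAP2	ENST00000295682	1.6	4.1	2.6
LINC01122	ENST00000427421	11.2	29	2.6			7mA1
ACTG1P20	ENSG00000241547	1.3	3.2	2.5
lnc-KRTAP5-10-1	lnc-KRTAP5-10-1:1	1.5	3.5	2.4			7m8
MT1E	ENST00000306061	1.1	2.8	2.4				yes
NUDT19	ENST00000397061	1.0	2.5	2.4			7mA1
PRDX4	ENST00000379341	1.0	2.4	2.4				yes
TMEM258	ENST00000537328	1.1	2.6	2.4
XLOC_l2_005952	TCONS_l2_00011050	6.6	15.6	2.4		7m8
BTG3	ENST00000629582	1.6	3.7	2.3				yes
EVI5L	ENST00000270530	1.3	3.0	2.3
LINC01534	ENST00000433232	1.0	2.3	2.3
lnc-ADA-1	lnc-ADA-1:2	1.0	2.3	2.3
lnc-ZNF431-4	lnc-ZNF431-4:1	1.1	2.6	2.3
MT1A	ENST00000290705	2.5	5.6	2.3				yes
CSRP2	ENST00000311083	2.7	5.9	2.2
FYCO1	ENST00000296137	1.0	2.2	2.2			7m8
HYAL3	ENST00000336307	2.0	4.3	2.2
KCNQ1	ENST00000632153	1.0	2.2	2.2
lnc-RP11-158I9.5.1-2	TCONS_00019776	1.5	3.3	2.2
PCNX	ENST00000304743	3.8	8.3	2.2		7mA1/8m
PRSS36	ENST00000268281	1.4	2.8	2.2
SMARCA4	ENST00000344626	1.0	2.2	2.2		7m8		yes
TNRC6C	ENST00000335749	8.5	18.3	2.2		7m8
TOLLIP	ENST00000317204	1.3	2.8	2.2			7mA1
ARF4	ENST00000303436	1.0	2.1	2.1				yes
ATG4D	ENST00000309469	1.4	2.8	2.1				yes
CSE1L	ENST00000262982	1.2	2.5	2.1				yes
lnc-PCF11-1	lnc-PCF11-1:12	1.5	3.2	2.1
MARS	ENST00000262027	1.7	3.6	2.1
NANS	ENST00000210444	1.0	2.1	2.1
ORMDL2	ENST00000243045	1.1	2.3	2.1
PFKFB2	ENST00000367080	1.4	3.0	2.1		7m8	7mA1
PGM2L1	ENST00000298198	1.8	3.7	2.1
PTPN23	ENST00000265562	1.5	3.1	2.1
TSACC	ENST00000368255	1.5	3.1	2.1
TUBA1C	ENST00000301072	1.1	2.4	2.1		7mA1		yes
XLOC_l2_013031	TCONS_l2_00024809	6.5	13.7	2.1
C15orf61	ENST00000342683	1.3	2.6	2.0			8m
LAT	ENST00000360872	1.0	2.0	2.0
LOC101929494	N/A	1.6	3.2	2.0
MYCBP	ENST00000397572	1.5	3.1	2.0			7mA1
NDRG4	ENST00000394279	1.1	2.2	2.0				yes
TUBE1	ENST00000368662	1.1	2.2	2.0				yes
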