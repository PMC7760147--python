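gene	transcript	ratio_denominator	ratio_numerator	fc_printed	sites_5utr	sites_cds	sites_3utr	growth_go
IRAK4	ENST00000613694	1.0	4.6	4.6		8m		yes
CDKN2A	ENST00000304494	1.0	4.0	4.0				yes
JPX	ENST00000415215	1.5	5.8	3.9			8m
PLGRKT	ENST00000223864	1.0	3.0	3.0	8m
TMEM245	ENST00000374586	1.0	2.9	2.9			7m8/8m
TOMM6	ENST00000398884	1.5	4.1	2.7
CDK1	ENST00000395284	1.0	2.6	2.6				yes
FAM117A	ENST00000240364	1.4	3.6	2.6
WDR83OS	ENST00000596731	1.3	3.2	2.5	7m8
CCNK	ENST00000389879	1.0	2.4	2.4		8m		yes
MYCBP	ENST00000397572	2.3	5.4	2.3			7mA1
RNF34	ENST00000392465	1.3	3.0	2.3				yes
UBC	ENST00000339647	1.0	2.3	2.3				yes
POP4	ENST00000585603	1.0	2.3	2.3
MNT	ENST00000174618	1.2	2.7	2.3		7m8	7mA1	yes
HSPB1	ENST00000248553	1.8	3.9	2.2	7mA1			yes
INAFM1	ENST00000552360	1.3	2.8	2.2
PCNA	ENST00000379160	1.0	2.1	2.1				yes
SP100	ENST00000264052	1.2	2.5	2.1
RPP25L	ENST00000297613	1.2	2.4	2.0
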