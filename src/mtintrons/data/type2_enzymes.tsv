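name	site	cut_top	cut_bottom
AatII	GACGTC	5	1
AccI	GTMKAC	2	4
AflII	CTTAAG	1	5
AgeI	ACCGGT	1	5
AluI	AGCT	2	2
AlwNI	CAGNNNCTG	6	3
ApaI	GGGCCC	5	1
ApoI	RAATTY	1	5
AscI	GGCGCGCC	2	6
AseI	ATTAAT	2	4
AvaI	CYCGRG	1	5
AvrII	CCTAGG	1	5
BamHI	GGATCC	1	5
BanI	GGYRCC	1	5
BclI	TGATCA	1	5
BglI	GCCNNNNNGGC	7	4
BglII	AGATCT	1	5
BsiWI	CGTACG	1	5
BspHI	TCATGA	1	5
BsrGI	TGTACA	1	5
BstBI	TTCGAA	2	4
BstXI	CCANNNNNNTGG	8	4
ClaI	ATCGAT	2	4
DdeI	CTNAG	1	4
DraI	TTTAAA	3	3
DraIII	CACNNNGTG	6	3
EagI	CGGCCG	1	5
EcoRI	GAATTC	1	5
EcoRV	GATATC	3	3
FseI	GGCCGGCC	6	2
HaeIII	GGCC	2	2
HhaI	GCGC	3	1
HindIII	AAGCTT	1	5
HinfI	GANTC	1	4
HpaI	GTTAAC	3	3
KpnI	GGTACC	5	1
MfeI	CAATTG	1	5
MluI	ACGCGT	1	5
MseI	TTAA	1	3
MspI	CCGG	1	3
NaeI	GCCGGC	3	3
NarI	GGCGCC	2	4
NcoI	CCATGG	1	5
NdeI	CATATG	2	4
NheI	GCTAGC	1	5
NotI	GCGGCCGC	2	6
NruI	TCGCGA	3	3
NsiI	ATGCAT	5	1
PacI	TTAATTAA	5	3
PflMI	CCANNNNNTGG	7	4
PmeI	GTTTAAAC	4	4
PstI	CTGCAG	5	1
PvuI	CGATCG	4	2
PvuII	CAGCTG	3	3
RsaI	GTAC	2	2
SacI	GAGCTC	5	1
SacII	CCGCGG	4	2
SalI	GTCGAC	1	5
Sau3AI	GATC	0	4
SbfI	CCTGCAGG	6	2
ScaI	AGTACT	3	3
SmaI	CCCGGG	3	3
SnaBI	TACGTA	3	3
SpeI	ACTAGT	1	5
SphI	GCATGC	5	1
SspI	AATATT	3	3
StuI	AGGCCT	3	3
StyI	CCWWGG	1	5
SwaI	ATTTAAAT	4	4
TaqI	TCGA	1	3
XbaI	TCTAGA	1	5
XhoI	CTCGAG	1	5
XmaI	CCCGGG	1	5
ZraI	GACGTC	3	3
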