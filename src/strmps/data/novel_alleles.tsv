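locus	lb_allele	name	count
FGA	26	FGA [CE26]-Chr4-GRCh38 154,587,736–154,587,823 [GGAA]2 GGAG [AAAG]16 AGAG AAAG AGAA AAAA [GAAA]3	1
FGA	27	FGA [CE27]-Chr4-GRCh38 154,587,736–154,587,823 [GGAA]2 GGAG [AAAG]17 AGAG AAAG AGAA AAAA [GAAA]3	1
FGA	29	FGA [CE29]-Chr4-GRCh38 154,587,736–154,587,823 [GGAA]2 GGAG [AAAG]19 AGAG AAAG AGAA AAAA [GAAA]3	1
D6S1043	16	D6S1043 [CE16]-Chr6-GRCh38 91,740,225–91,740,272 [ATCT]16	1
D6S1043	19.3	D6S1043 [CE19.3]-Chr6-GRCh38 91,740,225–91,740,272 [ATCT]5 ATGT [ATCT]2 ATC [ATCT]11 91,740,273-A	1
D7S820	10.1	D7S820 [CE10.1]-Chr7-GRCh38 84,160,226–84,160,277 [TATC]10 84,160,204-A; 84,160,204.1A	1
D7S820	11	D7S820 [CE11]-Chr7-GRCh38 84,160,226–84,160,277 [TATC]9 TGTC TATC 84,160,204-A	1
D8S1179	8	D8S1179 [CE8]-Chr8-GRCh38 124,894,865–124,894,916 [TCTA]7 TCAA	1
vWA	16	vWA [CE16]-Chr12-GRCh38 5,983,977–5,984,044 [TAGA]10 [CAGA]5 TAGA	4
vWA	17	vWA [CE17]-Chr12-GRCh38 5,983,977–5,984,044 [TAGA]12 [CAGA]4 CAGA	1
D12S391	25	D12S391 [CE25]-Chr12-GRCh38 12,297,020–12,297,095 [AGAT]16 [AGAC]3 AGAA [AGAC]4 AGAT	2
D16S539	8	D16S539 [CE8]-Chr16-GRCh38 86,352,702–86,352,745 [GATA]8 86,352,692-G	3
D16S539	8	D16S539 [CE8]-Chr16-GRCh38 86,352,702–86,352,745 [GATA]8 86,352,761-C	1
D19S433	12.2	D19S433 [CE12.2]-Chr19-GRCh38 29,926,235–29,926,298 [CCTT]11 cctt CCTT tt CCTT	1
D21S11	28	D21S11 [CE28]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]5 [TCTG]5 [TCTA]3 ta [TCTA]2 tca [TCTA]2 tccata [TCTA]11	2
D21S11	29	D21S11 [CE29]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]7 [TCTG]4 [TCTA]3 ta [TCTA]3 tca [TCTA]2 tccata [TCTA]10	1
D21S11	29	D21S11 [CE29]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]6 [TCTG]5 [TCTA]3 ta [TCTA]3 tca [TCTA]2 tccata [TCTA]10 19,182,101-T	2
D21S11	32.2	D21S11 [CE32.2]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]5 [TCTG]7 [TCTA]3 ta [TCTA]3 tca [TCTA]2 tccata [TCTA]11 TA TCTA	1
D21S11	33.2	D21S11 [CE33.2]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]5 [TCTG]6 [TCTA]3 ta [TCTA]4 tca [TCTA]2 tccata [TCTA]12 TA TCTA	2
DYS481	29	DYS481 [CE29]-ChrY-GRCh38 8,558,337–8,558,402 [CTT]29 8,558,336-T	1
DYS612	36	DYS612 [CE36]-ChrY-GRCh38 13,640,728–13,640,835 [CCT]5 CTT [TCT]4 CCT [TCT]25 13,640,861-C	1
DYS390	23	DYS390 [CE23]-ChrY-GRCh38 15,163,067–15,163,162 [TAGA]4 CAGA [TAGA]9 [CAGA]9 15,163,163-C	1
DYS390	26	DYS390 [CE26]-ChrY-GRCh38 15,163,067–15,163,162 [TAGA]4 CAGA [TAGA]12 [CAGA]9	2
DYS390	27	DYS390 [CE27]-ChrY-GRCh38 15,163,067–15,163,162 [TAGA]4 CAGA [TAGA]13 [CAGA]9	1
DYS390	27	DYS390 [CE27]-ChrY-GRCh38 15,163,067–15,163,162 [TAGA]4 CAGA [TAGA]12 [CAGA]10	3
Y-GATA-H4	10	Y-GATA-H4 [CE10]-ChrY-GRCh38 16,631,673–16,631,720 [TCTA]10 16,631,756-G	7
Y-GATA-H4	11	Y-GATA-H4 [CE11]-ChrY-GRCh38 16,631,673–16,631,720 [TCTA]11 16,631,756-G	15
Y-GATA-H4	12	Y-GATA-H4 [CE12]-ChrY-GRCh38 16,631,673–16,631,720 [TCTA]12 16,631,756-G	1
DYS460	9	DYS460 [CE9]-ChrY-GRCh38 18,888,956–18,888,995 [CTAT]9 18,888,914-T; 18,888,949-T	1
DYS448	17	DYS448 [CE17]-ChrY-GRCh38 22,218,923–22,219,078 [AGAGAT]10 N42 [AGAGAT]7	4
DYS448	17	DYS448 [CE17]-ChrY-GRCh38 22,218,923–22,219,078 [AGAGAT]9 N42 [AGAGAT]8	1
DYS448	18	DYS448 [CE18]-ChrY-GRCh38 22,218,923–22,219,078 [AGAGAT]11 N36 [AGAGAT]8 22,218,995–22,219,000 DEL	1
DYF387S1	39	DYF387S1 [CE39]-ChrY-GRCh38 25,884,581–25,884,724 [CTTT]18 [CTTC]8 [CTTT]2 CTTC [CTTT]2 [CTTC]4 CTAC [CTTT]3	2
DXS8378	10	DXS8378 [CE10]-ChrX-GRCh38 9,402,262–9,402,301 [ATAG]10 9,402,257-G	1
DXS8378	10	DXS8378 [CE10]-ChrX-GRCh38 9,402,262–9,402,301 [ATAG]5 ACAG [ATAG]4	1
DXS7132	10	DXS7132 [CE10]-ChrX-GRCh38 65,435,647–65,435,702 [TAGA]10	1
DXS10074	15.3	DXS10074 [CE15.3]-ChrX-GRCh38 67,757,345–67,757,400 [AAGA]10 AAA [AAGA]2 AAGG [AAGA]2	4
DXS10074	16.3	DXS10074 [CE16.3]-ChrX-GRCh38 67,757,345–67,757,400 [AAGA]11 AAA [AAGA]2 AAGG [AAGA]2	2
DXS10103	21	DXS10103 [CE21]-ChrX-GRCh38 134,284,959–134,285,038 [TAGA]2 ctga CAGA [TAGA]13 [CAGA]4 TAGA	4
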