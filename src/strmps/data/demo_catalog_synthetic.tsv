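locus	isfg_name
FGA	FGA [CE22]-Chr4-GRCh38 154,587,736–154,587,823 [GGAA]2 GGAG [AAAG]12 AGAG AAAG AGAA AAAA [GAAA]3
D6S1043	D6S1043 [CE12]-Chr6-GRCh38 91,740,225–91,740,272 [ATCT]12
D7S820	D7S820 [CE13]-Chr7-GRCh38 84,160,226–84,160,277 [TATC]13
D8S1179	D8S1179 [CE13]-Chr8-GRCh38 124,894,865–124,894,916 [TCTA]13
vWA	vWA [CE17]-Chr12-GRCh38 5,983,977–5,984,044 [TAGA]11 [CAGA]5 TAGA
D12S391	D12S391 [CE19]-Chr12-GRCh38 12,297,020–12,297,095 [AGAT]11 [AGAC]7 AGAT
D16S539	D16S539 [CE11]-Chr16-GRCh38 86,352,702–86,352,745 [GATA]11
D19S433	D19S433 [CE13.2]-Chr19-GRCh38 29,926,235–29,926,298 [CCTT]12 cctt CCTT tt CCTT
D21S11	D21S11 [CE29]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]6 [TCTG]5 [TCTA]3 ta [TCTA]3 tca [TCTA]2 tccata [TCTA]10
D22S1045	D22S1045 [CE16]-Chr22-GRCh38 37,141,011–37,141,058 [ATT]13 ACT [ATT]2
DYS481	DYS481 [CE22]-ChrY-GRCh38 8,558,337–8,558,402 [CTT]22
DYS612	DYS612 [CE36]-ChrY-GRCh38 13,640,728–13,640,835 [CCT]5 CTT [TCT]4 CCT [TCT]25
DYS390	DYS390 [CE24]-ChrY-GRCh38 15,163,067–15,163,162 [TAGA]4 CAGA [TAGA]10 [CAGA]9
Y-GATA-H4	Y-GATA-H4 [CE12]-ChrY-GRCh38 16,631,673–16,631,720 [TCTA]12
DYS460	DYS460 [CE10]-ChrY-GRCh38 18,888,956–18,888,995 [CTAT]10
DYS448	DYS448 [CE19]-ChrY-GRCh38 22,218,923–22,219,078 [AGAGAT]11 N42 [AGAGAT]8
DYF387S1	DYF387S1 [CE36]-ChrY-GRCh38 25,884,581–25,884,724 [CTTT]15 [CTTC]8 [CTTT]2 CTTC [CTTT]2 [CTTC]4 CTAC [CTTT]3
DXS8378	DXS8378 [CE10]-ChrX-GRCh38 9,402,262–9,402,301 [ATAG]10
DXS7132	DXS7132 [CE14]-ChrX-GRCh38 65,435,647–65,435,702 [TAGA]14
DXS10074	DXS10074 [CE17.3]-ChrX-GRCh38 67,757,345–67,757,400 [AAGA]12 AAA [AAGA]2 AAGG [AAGA]2
DXS10103	DXS10103 [CE19]-ChrX-GRCh38 134,284,959–134,285,038 [TAGA]2 ctga CAGA [TAGA]11 [CAGA]4 TAGA
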