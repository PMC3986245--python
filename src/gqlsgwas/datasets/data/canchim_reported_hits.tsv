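trait	snp_id	chromosome	position_bp	alleles	genes	region	maf	p_value	fdr_tier	effect
BW	rs43421095	4	117400491	A,C	DPP6	Intron	0.2957	1.39E-06	5%	-0.5929
BW	rs135754703	9	55075535	A,C	LOC783932;MANEA	Intergenic	0.4552	8.22E-06	10%	-0.41612
BW	rs136146400	9	55078557	A,G	LOC783932;MANEA	Intergenic	0.4563	7.23E-06	10%	-0.41976
BW	rs109313268	9	55103057	T,C	LOC783932;MANEA	Intergenic	0.4962	3.98E-06	10%	-0.44946
WW	rs43421095	4	117400491	A,C	DPP6	Intron	0.2957	1.91E-07	1%	-2.84898
WW	rs135156506	6	35008291	T,C	FARSB	Upstream	0.1582	7.32E-07	5%	-2.17934
WW	rs135591504	6	41978318	T,C	KCNIP4	Intron	0.2273	2.74E-06	5%	1.55340
WW	rs136337296	11	103096174	T,C	GTF3C5	Intron	0.365	1.81E-05	10%	1.82227
WW	rs109348820	11	103154983	T,C	RALGDS	Intron	0.3916	2.02E-05	10%	1.76133
WW	rs133132366	11	103157389	T,C	RALGDS	Intron	0.4077	1.28E-05	10%	1.81074
WW	rs134657108	11	103162503	A,G	RALGDS	Intron	0.4177	1.26E-05	10%	1.90613
WW	rs136054783	11	103167055	A,G	RALGDS	Intron	0.4066	8.40E-06	10%	1.79279
WW	rs136961684	11	103170500	A,G	RALGDS	Intron	0.4076	1.08E-05	10%	-1.80009
WW	rs109945520	11	103171584	G,T	RALGDS	Intron	0.4047	1.17E-05	10%	1.80350
WW	rs109524492	11	103172572	C,T	RALGDS	Intron	0.4099	5.74E-06	10%	1.63200
WW	rs110048168	11	103174303	A,C	RALGDS	Intron	0.3886	3.05E-06	10%	-1.66682
LYW	rs29011435	7	28515652	T,C	MARCH3;LMNB1;PHAX;ALDH7A1;C7H5orf48;GRAMD3;MIR2458;LOC100848523	Intergenic	0.374	4.62E-06	10%	3.59660
LYW	rs134201365	7	28522539	T,G	MARCH3;LMNB1;PHAX;ALDH7A1;C7H5orf48;GRAMD3;MIR2458;LOC100848523	Intergenic	0.375	4.62E-06	10%	-3.59660
LYW	rs109581958	22	54624190	T,C	LARS2;LOC101907967;TMEM158;LOC101908013;CDCP1;LOC614114;LOC101908094;LOC101901958;ZDHHC3;EXOSC7;LOC100847326;CLEC3B	Intergenic	0.2335	1.09E-05	10%	-3.61775
LYW	rs110246286	22	54625467	T,C	LARS2;LOC101907967;TMEM158;LOC101908013;CDCP1;LOC614114;LOC101908094;LOC101901958;ZDHHC3;EXOSC7;LOC100847326;CLEC3B	Intergenic	0.2348	1.09E-05	10%	-3.61775
LYW	rs109242147	25	15697543	A,G	XYLT1	Intron	0.1192	1.26E-06	5%	3.24823
LYW	rs109646351	27	2614991	A,G	LOC101904868	Intron	0.4456	3.05E-05	10%	-3.91546
LYW	rs109822265	27	2619242	A,C	LOC101904868	Intron	0.4454	3.05E-05	10%	3.91546
LYW	rs110603636	27	2620088	A,C	LOC101904868	Intron	0.4456	3.05E-05	10%	3.91546
LYW	rs110994026	27	2620961	T,C	LOC101904868	Intron	0.4494	3.46E-05	10%	-3.85715
LYW	rs134791735	27	2623000	T,G	LOC101904868	Intron	0.4443	3.05E-05	10%	3.91546
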