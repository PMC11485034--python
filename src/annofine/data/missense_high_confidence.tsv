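variant_id	signal_id	sentinel_id	transcript_id	gene_symbol	chrom	pos	amino_acid_change	polyphen	sift	posterior	maf
rs709209	1_1	rs709209	ENST00000377939.4	RNF207	1	6278414	p.Asn573Ser	Ben	Tol low conf	0.997	0.342
rs1260326	34_1	rs1260326	ENST00000264717.2	GCKR	2	27730940	p.Leu446Pro	Ben	Tol	0.994	0.396
rs3100246	35_1	rs3100246	ENST00000401605.1	CLIP4	2	29383256	p.Arg486Leu	Ben	Del	0.998	0.152
rs17362588	51_3	rs17362588	ENST00000343876.2	CCDC141	2	179721046	p.Arg379Trp	Prob Dam	Del	0.978	0.088
rs10497529	51_5	rs10497529	ENST00000420890.2	CCDC141	2	179839888	p.Ala141Val	Prob Dam	Del	1.000	0.037
rs4833772	96_1	rs4833772	ENST00000424958.1	AC079341.1	4	122687491	p.Asp98His	Unknown	-	0.790	0.488
rs28925904	97_1	rs28925904	ENST00000262995.4	GAB1	4	144359490	p.Pro311Leu	Poss dam	Del	0.990	0.025
rs2307111	106_1	rs2307111	ENST00000428202.2	POC5	5	75003678	p.His36Arg	Ben	Tol	1.000	0.395
rs12514461	108_1	rs12514461	ENST00000446378.2	CMYA5	5	79041057	p.Lys3583Glu	Poss dam	Tol	0.940	0.116
rs1015149	127_1	rs9471627	ENST00000230323.4	TFEB	6	41658889	p.His21Gln	-	-	0.803	0.459
rs80095409	147_1	rs150990106	ENST00000393561.1	LAMB1	7	107600211	p.Arg819Gly	Prob Dam	Del	0.709	0.014
rs6271	175_2	rs6271	ENST00000393056.2	DBH	9	136522274	p.Arg549Cys	Poss dam	Tol	0.990	0.074
rs7102584	205_3	rs7102584	ENST00000338350.4	KCNJ5	11	128782012	p.Gln282Glu	Ben	Tol	0.999	0.018
rs3184504	221_2	rs10774625	ENST00000538307.1	SH2B3	12	111884608	p.Trp60Arg	Ben	Del	0.701	0.481
rs12889267	230_1	rs12889267	ENST00000555038.1	ARHGEF40	14	21542766	p.Lys293Glu	Poss dam	Del	1.000	0.167
rs365990	231_1	rs365990	ENST00000356287.3	MYH6	14	23861811	p.Val1101Ala	Ben	Tol	1.000	0.370
rs5742915	243_4	rs5742915	ENST00000268058.3	PML	15	74336633	p.Phe645Leu	Ben	Tol	1.000	0.461
rs238238	258_1	rs238238	ENST00000323997.6	ENO3	17	4856376	p.Asn71Ser	Ben	Tol low conf	0.680	0.296
rs61735998	276_3	rs61735998	ENST00000590592.1	FHOD3	18	34289285	p.Val822Phe	Poss dam	Del	1.000	0.025
rs7412	290_1	rs190712692	ENST00000252486.4	APOE	19	45412079	p.Arg176Cys	Prob Dam	Del	0.810	0.081
rs17265513	297_1	rs17265513	ENST00000544979.2	ZHX3	20	39832628	p.Asn310Ser	Poss dam	Tol	0.979	0.199
rs148377517	298_1	rs148377517	ENST00000396825.3	FITM2	20	42939693	p.Met32Ile	Ben	Tol	1.000	0.015
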