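trait	snp	chrom	pos	maf	gene	mutation_type	p_trait	p_trait_replication	p_eqtl	p_de	p_smr	p_heidi	m6a_id	m6a_pos	m6a_effect
AIS	rs2013162	1	209968684	0.3736	IRF6	Syn	1.27E-04	6.73E-04	6.30E-23	6.15E-03	3.64E-04	0.11	m6A_ID_132331	209968661	Loss
AIS	rs13196003	6	24535999	0.0725	ALDH5A1	UTR3	1.29E-04	3.36E-04					m6A_ID_189376	24535978	Loss
AIS	rs1322257	9	114480562	0.0112	C9orf84	Nonsyn	1.02E-04	8.28E-03					m6A_ID_226979	114480545	Gain
AIS	rs10760214	9	125002246	0.4763	RBM18	UTR3	7.54E-05	6.38E-04	1.29E-35		2.44E-03		m6A_ID_227927	125002247	Loss
AIS	rs10832778	11	17394073	0.3885	NCR3LG1	UTR3	4.25E-05	3.97E-04	1.18E-17				m6A_ID_244519	17394071	Gain
AIS	rs5213	11	17408404	0.3615	KCNJ11	UTR3	2.46E-05	4.49E-04	7.57E-13		7.21E-04		m6A_ID_27449	17408423	Loss
AIS	rs7398833	12	111786892	0.2509	CUX2	UTR3	1.78E-05	2.46E-05		1.51E-02			m6A_ID_265695	111786917	Gain
AIS	rs11076256	16	58752466	0.0818	GOT2	Nonsyn	1.29E-04	3.46E-03					m6A_ID_43360	58752472	Loss
AIS	rs11559309	17	1556911	0.0374	PRPF8	Syn	6.18E-06	7.83E-06					m6A_ID_301320	1556907	Gain
LAS	rs11121484	1	9784423	0.0769	PIK3CD	Syn	1.40E-04	1.18E-02		4.20E-02			m6A_ID_112617	9784425	Gain
LAS	rs116577362	5	140242897	0.0215	PCDHA	Nonsyn	1.04E-04	1.04E-04					m6A_ID_184329	140242899	Loss
LAS	rs174535	11	61551356	0.3392	MYRF	Nonsyn	1.31E-04	6.05E-05					m6A_ID_247771	61551331	Gain
LAS	rs17875563	15	81604293	0.2405	IL16	UTR3	1.67E-04	1.83E-03	9.52E-09		3.97E-02		m6A_ID_287576	81604291	Gain
CES	rs2273235	5	149907533	0.4821	NDST1	Syn	3.99E-04	1.04E-03	3.23E-07	2.65E-02	8.47E-03	0.65	m6A_ID_185695	149907528	Loss
SVS	rs1887812	1	92414993	0.2074	BRDT	UTR5	4.05E-04	8.51E-04					m6A_ID_121270	92414991	Loss
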