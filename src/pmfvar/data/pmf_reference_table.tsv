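gene	cdna_change	protein_change	rsid	gnomad_fin_af	finrisk_af	n_carriers	sift	polyphen2	cadd	mutation_taster	varity_r	mutscore	or_reported	ci_low_reported	ci_high_reported	p_reported	adj_p_reported	functional_class
HPSE	c.1294C>T	p.Arg432Ter	rs141973931	0.0045	0.0026	3	NA	NA	44.0	DC	NA	NA	4.52	1.16	17.59	0.029	0.054	Extracellular matrix
CRTAC1	c.457C>T	p.Arg153Cys	rs140424345	0.0041	0.0023	3	D	PD	32.0	NA	0.386	0.764	5.27	1.31	21.22	0.019	0.042	Extracellular matrix
NMRK2	c.242C>T	p.Pro81Leu	rs146474422	0.0049	0.0042	3	D	PD	23.8	NA	0.286	0.508	2.85	0.79	10.28	0.110	0.126	Extracellular matrix
LIMS1	c.301G>A	p.Ala101Thr	rs145559017	0.0030	0.0005	3	D	PD	27.1	NA	0.258	0.186	22.65	2.35	218.58	0.007	0.019	Extracellular matrix
FRAS1	c.10426G>A	p.Val3476Met	rs201963922	0.0011	0.0012	3	D	PD	25.4	NA	NA	0.421	10.33	2.07	51.45	0.004	0.014	Extracellular matrix
TGM6	c.419G>A	p.Cys140Tyr	rs146485197	0.0029	0.0049	3	D	PoD	25.3	NA	0.38	0.362	2.43	0.69	8.57	0.169	0.169	Extracellular matrix
TNS2	c.3848G>A	p.Gly1283Asp	rs200670407	0.0038	0.0027	3	D	PD	28.6	NA	0.94	0.638	4.52	1.16	17.57	0.029	0.054	Extracellular matrix
MYBPHL	c.193C>T	p.Arg65Trp	rs146641385	0.0042	0.0042	3	D	PoD	23.9	NA	0.35	0.446	2.87	0.8	10.36	0.107	0.126	Cardiomyocytes/Contractility
UNC45B	c.2143C>T	p.Arg715Trp	rs141654082	0.0008	NA	3	D	PD	25.5	NA	0.783	0.785	14.98	4.42	50.73	1.7e-5	0.0004	Cardiomyocytes/Contractility
UNC45A	c.1309G>T	p.Gly437Cys	rs146513919	0.0014	0.0019	4	D	PD	31.0	NA	0.896	0.873	8.48	2.26	31.77	0.002	0.011	Cardiomyocytes/Contractility
CAPN1	c.302G>C	p.Gly101Ala	rs534135243	0.0019	0.0019	3	D	PD	31.0	NA	0.941	0.922	6.33	1.5	26.65	0.012	0.029	Cardiac hypertrophy
NRIP1	c.717A>T	p.Arg239Ser	rs202001270	0.0015	0.0049	3	D	PD	23.6	NA	0.937	0.573	2.43	0.69	8.57	0.169	0.169	Cardiac hypertrophy
OMA1	c.1093G>T	p.Asp365Tyr	rs77980955	0.0029	0.0038	3	D	PD	28.2	NA	0.857	0.858	3.16	0.86	11.56	0.082	0.120	Cardiac mitochondria
HK2	c.1057C>T	p.Arg353Cys	rs61748096	0.0041	0.0030	3	D	PD	23.3	NA	0.336	0.242	3.95	1.04	15	0.043	0.073	Cardiac mitochondria
TLR3	c.889C>G	p.Leu297Val	rs35311343	0.0009	0.0008	3	D	PD	22.9	NA	0.637	0.156	15.85	2.64	95.3	0.003	0.011	Immunity/Inflammation
CCL22	c.230C>A	p.Ala77Asp	rs777890031	0.0013	0.0042	3	D	PD	23.3	NA	0.787	0.522	2.87	0.8	10.36	0.107	0.126	Immunity/Inflammation
SYT9	c.1057C>G	p.Leu353Val	rs117876446	0.0039	0.0043	3	D	PD	25.0	NA	0.457	0.442	2.81	0.78	10.14	0.114	0.126	Other
MTUS2	c.637C>T	p.Arg213Trp	rs201600406	0.0049	0.0035	5	D	PoD	22.5	NA	NA	NA	5.75	1.91	17.3	0.002	0.011	Other
PLB1	c.2698G>A	p.Val900Met	rs142314104	0.0004	0.0008	3	D	PD	25.4	NA	0.256	0.05	15.85	2.64	95.3	0.003	0.011	Other
WNT8B	c.359G>T	p.Gly120Val	rs200171146	0.0016	0.0012	3	D	PD	28.8	NA	0.963	0.868	10.34	2.08	51.49	0.004	0.014	Other
VASN	c.889C>T	p.Arg297Cys	rs148092711	0.0038	0.0036	3	D	PoD	26.2	NA	0.109	0.241	3.3	0.99	11.04	0.052	0.082	Other
GPR17	c.428T>C	p.Met143Thr	rs202004329	0.0045	0.0039	3	D	PD	26.4	NA	0.916	0.763	3.07	0.84	11.24	0.089	0.123	Other
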