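SNP	effect_allele	other_allele	beta	eaf	se	pval	f_stat	gene	consequence
rs10465114	A	G	0.0625	0.2203	0.010874	9.04E-09	33.0371	RALGPS1	Intron Variant
rs1046934	A	C	0.0712	0.6493	0.009409	3.81E-14	57.2656	TSEN15	Missense Variant
rs10492367	T	G	0.1147	0.1983	0.01128	2.75E-24	103.3942	NA	NA
rs10831477	T	G	0.0704	0.8137	0.011579	1.20E-09	36.9643	MAML2	Intron Variant
rs10940168	A	G	-0.0534	0.3942	0.009248	7.74E-09	33.3399	LOC105379013	Intron Variant
rs11164653	T	C	-0.0799	0.4131	0.009162	2.77E-18	76.0472	COL11A1	Intron Variant
rs111844273	A	G	0.2317	0.0209	0.032524	1.05E-12	50.7499	HDAC9	Intron Variant
rs11727676	T	C	-0.0849	0.901	0.015484	4.18E-08	30.0658	HHIP	Synonymous Variant
rs12160491	A	G	-0.0614	0.7047	0.009839	4.37E-10	38.9408	NA	NA
rs12209223	A	C	0.1398	0.1117	0.014341	1.88E-22	95.0265	LOC101928540	Non Coding Transcript Variant
rs13302198	T	C	0.0544	0.6445	0.009918	4.14E-08	30.0826	DELEC1	Intron Variant
rs17677724	T	C	0.0723	0.1611	0.012245	3.54E-09	34.8641	LOC105379168	Intron Variant
rs1809889	T	C	0.0596	0.2806	0.010098	3.58E-09	34.8379	NA	NA
rs189933136	T	C	0.114	0.8413	0.01458	5.33E-15	61.1343	GSDMC	Intron Variant
rs1913707	A	G	0.0677	0.6043	0.009197	1.82E-13	54.1855	LOC124900668	Non Coding Transcript Variant
rs2188730	A	G	0.0722	0.1505	0.012602	1.01E-08	32.8217	NA	NA
rs2268023	A	T	0.0678	0.4109	0.009184	1.56E-13	54.4978	ITIH1	Intron Variant
rs2416564	T	C	-0.0734	0.5981	0.009145	1.00E-15	64.4262	ASTN2	Intron Variant
rs2521348	T	C	0.0555	0.3908	0.009192	1.56E-09	36.4577	MAP2K6	Intron Variant
rs2605098	A	G	0.0651	0.3368	0.009488	6.83E-12	47.0768	LYPLAL1-AS1	Intron Variant
rs28567725	T	C	-0.0546	0.5732	0.009066	1.72E-09	36.2674	FTO	Intron Variant
rs2862851	T	C	0.0655	0.4653	0.009022	3.86E-13	52.7134	TGFA	Intron Variant
rs3740129	A	G	0.0547	0.4505	0.009099	1.84E-09	36.1413	CHST3	Missense Variant
rs4073717	T	G	-0.0672	0.2013	0.011277	2.54E-09	35.5117	FGF18	Intron Variant
rs4252548	T	C	0.2254	0.0276	0.028433	2.24E-15	62.8449	IL11	Missense Variant
rs4411121	T	C	0.0648	0.3137	0.009679	2.16E-11	44.8189	NA	NA
rs62578126	T	C	-0.0626	0.3619	0.009494	4.29E-11	43.4762	LMX1B-DT	Intron Variant
rs66989638	A	G	0.0789	0.1326	0.013477	4.79E-09	34.2739	ECRG4	Intron Variant
rs6786146	T	C	0.1156	0.9479	0.020567	1.90E-08	31.5909	VGLL4	Intron Variant
rs67924081	A	G	0.0642	0.7441	0.010441	7.80E-10	37.8083	EHBP1L1	upstream transcript variant
rs6855246	A	G	-0.1087	0.9277	0.01884	7.94E-09	33.2896	NA	NA
rs6908606	A	G	-0.0688	0.711	0.00991	3.86E-12	48.1931	SUPT3H	Intron Variant
rs7875152	A	C	-0.0935	0.1408	0.013129	1.07E-12	50.7184	LOC105376205	Intron Variant
rs788857	A	G	-0.0544	0.7004	0.009939	4.42E-08	29.9574	PRKG2	Intron Variant
rs79056043	A	G	-0.1136	0.9367	0.018937	1.99E-09	35.9842	LRIG3	Intron Variant
rs79220007	T	C	-0.1059	0.9265	0.017705	2.22E-09	35.7745	HFE	3 Prime UTR Variant
rs798756	T	C	-0.0683	0.1936	0.011422	2.24E-09	35.7544	SLBP	Intron Variant
rs9475400	T	C	0.1084	0.0987	0.015138	8.03E-13	51.2748	BMP5	Intron Variant
rs9835230	A	G	0.0638	0.2433	0.010523	1.34E-09	36.7555	P3H2	Intron Variant
rs9976458	T	G	0.0628	0.2329	0.01125	2.37E-08	31.1624	ERG	Intron Variant
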