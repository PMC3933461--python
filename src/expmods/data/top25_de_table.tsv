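entrez_id	symbol	avexp_control	avexp_case	logfc	t	p	q
8318	CDC45L	-10.60497055	6.888526437	17.4935	29.62106	3.38E-12	2.44E-08
6768	ST14	-10.60497055	4.485981521	15.09095	20.89494	1.73E-10	6.25E-07
150468	CKAP2L	-10.60497055	5.637801523	16.24277	19.80968	3.14E-10	7.56E-07
7076	TIMP1	13.0689603	14.25878751	1.189827	10.94989	2.02E-07	0.000318
22822	PHLDA1	5.587196746	8.027978339	2.440782	10.86172	2.20E-07	0.000318
10184	LHFPL2	7.917215388	9.290336816	1.373121	10.38349	3.53E-07	0.000426
6262	RYR2	7.631018078	5.17677854	-2.45424	-9.46391	9.23E-07	0.000927
5122	PCSK1	-5.768921911	4.842599755	10.61152	9.366506	1.03E-06	0.000927
51659	GINS2	2.717290548	7.332656805	4.615366	9.13514	1.33E-06	0.001042
25907	TMEM158	6.047223743	9.527182627	3.479959	9.059868	1.44E-06	0.001042
134553	C5orf24	8.186755599	6.533418616	-1.65334	-8.56449	2.54E-06	0.001672
3717	JAK2	8.57895724	6.802215907	-1.77674	-8.35271	3.27E-06	0.001969
65055	REEP1	9.588972723	5.917460093	-3.67151	-8.07974	4.54E-06	0.002356
10098	TSPAN5	6.806365429	8.258852748	1.452487	8.076383	4.56E-06	0.002356
79875	THSD4	5.94390384	4.081214951	-1.86269	-7.91683	5.56E-06	0.002555
1894	ECT2	4.61023265	6.977634015	2.367401	7.902448	5.66E-06	0.002555
91057	CCDC34	6.09221058	8.336252794	2.244042	7.849065	6.04E-06	0.00257
51660	BRP44L	10.0463896	8.971708734	-1.07468	-7.62843	7.98E-06	0.003019
7407	VARS	5.131741292	6.826224311	1.694483	7.576624	8.53E-06	0.003019
27246	RNF115	10.0887354	8.477502335	-1.61123	-7.56481	8.66E-06	0.003019
8317	CDC7	4.496631066	6.438868807	1.942238	7.550876	8.82E-06	0.003019
64943	NT5DC2	6.258132602	8.79440855	2.536276	7.507439	9.32E-06	0.003019
646993	LOC646993	2.044714874	5.264715435	3.220001	7.484235	9.61E-06	0.003019
25805	BAMBI	10.45604266	8.230870464	-2.22517	-7.41575	1.05E-05	0.003161
10105	PPIF	-8.4927706	3.706250953	12.19902	7.360952	1.13E-05	0.003233
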