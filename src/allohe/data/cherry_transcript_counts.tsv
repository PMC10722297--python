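chromosome	subgenome	n_transcripts	n_from_f	n_from_a	n_shared_both	frac_higher_f	frac_tie	frac_higher_a
chr1_a	a	10675	6162	3953	2934	0.12	0.07	0.81
chr2_a	a	6511	3757	2301	1713	0.18	0.09	0.73
chr3_a	a	5597	3248	2019	1491	0.17	0.07	0.76
chr4_a	a	4969	2830	1743	1281	0.19	0.07	0.74
chr5_a	a	4446	2575	1627	1242	0.15	0.05	0.80
chr6_a	a	6963	4212	2555	1986	0.19	0.07	0.74
chr7_a	a	5280	3025	1969	1418	0.21	0.07	0.72
chr8_a	a	5257	3100	1860	1360	0.21	0.11	0.68
chr1_f	f	10133	6345	3495	2835	0.56	0.09	0.35
chr2_f	f	6254	3865	2056	1602	0.53	0.13	0.34
chr3_f	f	5869	3686	1953	1564	0.61	0.09	0.30
chr4_f	f	5362	3296	1820	1411	0.61	0.09	0.29
chr5_f	f	4032	2511	1425	1172	0.64	0.07	0.29
chr6_f	f	6968	4512	2441	1981	0.60	0.09	0.31
chr7_f	f	5033	3201	1687	1312	0.60	0.09	0.31
chr8_f	f	4925	3158	1566	1230	0.61	0.12	0.28
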