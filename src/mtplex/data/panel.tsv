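site	hg	ancestral	derived	l_name	l_seq	h_name	h_seq	pcr_conc_uM	amplicon_bp	tail_ct	tail_extra_c	probe_seq	orientation	probe_conc_uM	frag_nt
12007	A2	G	A	L11984	CTAGTCACAGCCCTATACTCCCTCT	H12009	TGTTAATGTGGTGGGTGAGTGAGC	0.025	73	26	1	CCTCTACATATTTACCACAACACAATG	forward	0.015	80
3330	A2a	C	T	L03326	ACATACCCATGGCCAACCTCCT	H03339	GGAATGCCATTGCGATTAGAATGGGT	0.022	60	14	1	CCATGGCCAACCTCCTACT	forward	0.015	48
11365	A2b	T	C	L11359	GCCAACAACTTAATATGACTAGCTTACACA	H11381	GGGAGTCATAAGTGGAGTCCGTAAAGAGG	0.033	80	25	0	CAACTTAATATGACTAGCTTACACAATAGC	forward	0.020	80
16265	A2b1	A	G	L16262	ACTGCAACTCCAAAGCCACCCC	H16272	GGGTGGGTAGGTTTGTTGGTATCCT	0.011	56	15	0	ACTCCAAAGCCACCCCTC	forward	0.015	48
11177	B2	C	T	L11163	CCCACCTTGGCTATCATCACCCG	H11182	GTATGTGCCTGCGTTCAGGCGT	0.025	63	7	1	CCCGATGAGGCAACCAG	forward	0.020	32
16483	B2a	G	A	L16471	GCTCCGGGCCCATAACACTTGG	H16494	ACCCTGAAGTAGGAACCAGATGTCGG	0.030	70	21	0	ACCAGATGTCGGATACAGTTCA	reverse	0.020	64
6755	B2b	G	A	L06750	GTCTGAGCTATGATATCAATTGGCTTCC	H06789	TGCTCGTGTGTCTACGTCTATTCC	0.032	90	16	0	TGGTGTGCTCACACGATAAA	reverse	0.015	52
7241	B2c	A	G	L07224	TCCGGAATGCCCCGACGTTACT	H07243	ACAGATGATAGGATGTTTCATGTGGTGT	0.023	68	9	1	TCGGACTACCCCGATGC	forward	0.015	36
8875	B2d	T	C	L08864	TCCCCTTATGAGCGGGCACAGT	H08896	TGTGGTAAGAAGTGGGCTAGGGC	0.029	76	18	0	CGGGCACAGTGATTATAGGC	forward	0.015	56
6119	B2e	C	T	L06094	TCGTCACAGCCCATGCATTTGT	H06133	AGTCAGTTGCCAAAGCCTCCGA	0.031	76	22	0	CCAAAGCCTCCGATTATGAT	reverse	0.015	64
10535	B2f	T	C	L10528	AGCATTTACCATCTCACTTCTAGGAATACT	H10537	GTAGGGAGGATATGAGGTGTGAGC	0.031	62	16	0	GAGGATATGAGGTGTGAGCG	reverse	0.020	52
4820	B4b	G	A	L04816	GCCCCCTTTCACTTCTGAGTCCC	H04828	CCGGATGTCAGAGGGGTGCCTT	0.033	56	11	0	AGGGGTGCCTTGGGTAAC	reverse	0.020	40
8913	X2a	A	G	L08905	CGCTCTAAGATTAAAAATGCCCTAGCCC	H08915	AGGGGTGTAGGTGTGCCTTGTG	0.003	59	26	0	AATGCCCTAGCCCACTTCTT	forward	0.015	72
14783	M	T	C	L14774	ACCCCAATACGCAAAACTAACCCCC	H14804	TGTTGGATGGGGTGGGGAGGTC	0.031	76	26	0	CGCAAAACTAACCCCCTAATAAAA	forward	0.020	76
493	C1b	A	G	L00474	TTTCCCCTCCCACTCCCATACT	H00511	TAGCAGCGGTGTGTGTGTGCTG	0.033	73	1	1	ACTCCCATACTACTAATCTCATCAATACA	forward	0.025	32
12978	C1c1a	A	G	L12972	ACGCTAATCCAAGCCTCACCCCA	H12993	TTGGGCTGATTTGCCTGCTGCT	0.018	65	18	0	CCAAGCCTCACCCCACTACT	forward	0.015	56
14356	C1c2	C	T	L14348	ACCACAACCACCACCCCATCAT	H14371	TGGGGTTAGCGATGGAGGTAGGA	0.015	67	24	0	GTAGGATTGGTGCTGTGGGT	reverse	0.015	68
16051	C1d	A	G	L16049	TCTTTCATGGGGAAGCAGATTTGGG	H16065	AGCGGTTGTTGATGGGTGAGTC	0.019	62	11	0	GGGGAAGCAGATTTGGGT	forward	0.015	40
7697	C1d1	G	A	L07684	TGATCACGCCCTCATAATCATTTTCCTT	H07705	TGTTGTGAGTGTTAGGAAAAGGGCA	0.033	73	23	0	GTTAGGAAAAGGGCATACAGGA	reverse	0.020	68
14433	C4c	C	T	L14431	GACCTCAACCCCTGACCCCCAT	H14443	ACTACAGCGATGGCTATTGAGGAG	0.019	57	10	0	ACCCCTGACCCCCATG	forward	0.015	36
2092	D1	C	T	L02079	GCCCACAGAACCCTCTAAATCCCC	H02106	TCCTAGTGTCCAAAGAGCTGTTCCT	0.033	75	26	1	AGCTGTTCCTCTTTGGACTAACA	reverse	0.020	76
9667	D2a1	A	G	L09652	GGAGTATCAATCACCTGAGCTCACCA	H09670	GCAGTGCTTGAATTATTTGGTTTCGGT	0.032	70	24	1	CTTGAATTATTTGGTTTCGGTTG	reverse	0.020	72
4991	D2a2	G	A	L04976	TCATAGCAGGCAGTTGAGGTGGA	H05007	TCCTATGTGGGTAATTGAGGAGTATGC	0.032	88	20	0	GGTGGATTAAACCAAACCCA	forward	0.015	60
9181	D2b	A	G	L09159	TCGCTGTCGCCTTAATCCAAGCC	H09183	TGTGTTGTCGTGCAGGTAGAGG	0.032	68	12	1	TTGTCGTGCAGGTAGAGGC	reverse	0.015	44
10181	D4b1	C	T	L10177	AATCCACCCCTTACGAGTGCGG	H10197	TTATGGAGAAAGGGACGCGGGC	0.006	63	13	0	GGCGGGGGATATAGGGTC	reverse	0.015	44
6285	D4h3a	G	A	L06282	GCCGGAGCAGGAACAGGTTGAA	H06314	GTCTACGGAGGCTCCAGGGTGG	0.032	75	20	0	CCCTGCTAAGGGAGGGTAGA	reverse	0.020	60
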