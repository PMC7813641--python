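genus	clade	haplotype	accession	genome_bp	genome_gc	coding_bp	coding_gc	igr_bp	igr_gc	intronI_bp	intronI_n	intronII_bp	intronII_n	sir_bp_total	sir_bp_cr	sir_bp_igr	sir_n_total	sir_n_cr	sir_n_igr	tr_bp_total	tr_bp_cr	tr_bp_igr	tr_n_total	tr_n_cr	tr_n_igr
Polyplacotoma	-	H0	MH682141.1	23462	32.92	17690	32.18	5772	41.30	2299	4	41	1	192	114	78	15	8	7	343	70	273	5	3	5
Trichoplax	I	H1	NC_008151.2	43079	47.01	20276	38.21	22803	54.95	5129	8	80	2	5862	1167	4695	429	104	326	596	71	525	16	1	15
Trichoplax	I	H17	LC460470	43204	47.07	20313	38.31	22891	54.95	5108	8	80	2	5844	1227	4617	428	111	318	525	76	449	13	1	12
Trichoplax	I	H2	LC460468	44169	47.93	20260	38.38	23909	56.13	5967	8	80	2	7034	1193	5841	483	87	397	867	68	799	18	2	16
Trichoplax	II	H3	NC_008834.2	36699	44.18	19742	37.67	16957	51.77	6505	7	81	2	1808	460	1348	121	33	89	25	0	25	1	0	1
Hoilungia	III	H8	NC_008832.2	32661	39.22	19528	36.03	13133	43.95	4891	8	40	1	1748	791	957	115	51	64	168	42	126	6	1	5
Hoilungia	III	H23	MT957399	32980	39.14	19522	36.14	13458	43.49	3790	7	40	1	2102	835	1267	147	56	91	219	77	142	6	2	4
Hoilungia	IV	H19	LC460471	31779	40.23	19460	36.92	12319	45.46	4700	7	82	2	2433	724	1709	162	46	118	60	34	26	1	1	1
Hoilungia	V	H13	-	36537	40.32	19719	36.18	16818	45.17	4065	8	41	1	2916	748	2168	196	47	151	236	69	167	5	2	4
Hoilungia	V	H15	NC_015309.1	36676	40.40	19719	36.24	16957	45.24	3883	8	41	1	2793	746	2047	188	47	143	439	104	335	8	3	6
Hoilungia	V	H9	LC460472	36602	40.27	19694	36.18	16908	45.03	4055	8	41	1	2863	731	2132	191	46	147	330	70	260	6	2	5
Hoilungia	V	H4	NC_008833.2	37194	39.94	19616	36.08	17578	44.25	5116	8	41	1	2895	722	2173	208	48	162	221	72	149	6	2	5
Hoilungia	VII	H24	MT957400	33532	42.69	19765	38.14	13767	49.21	6178	8	46	1	3294	1150	2144	215	68	148	245	93	152	5	3	3
Hoilungia	VI	H11	LC460469	35188	38.61	19412	36.12	15776	41.67	4209	6	121	3	1673	539	1134	106	34	74	94	0	94	2	0	2
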