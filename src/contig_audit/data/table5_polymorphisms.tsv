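species	racon4_indels	racon4_hom_snps	racon4_het_snps	pilon6_indels	pilon6_hom_snps	pilon6_het_snps	racon3_pilon3_indels	racon3_pilon3_hom_snps	racon3_pilon3_het_snps
D. ananassae	107558	36905	10643	4189	294	45486	1056	445	10215
D. biarmipes	256004	67310	70947	9646	593	123890	5341	1306	73149
D. bipectinata	310109	114548	654543	71581	3173	655658	59176	5056	674390
D. erecta	209290	45382	22186	2758	289	37946	1150	435	22179
D. eugracilis	313426	85150	712410	75480	3359	708483	67204	5024	740846
D. mauritiana	131501	38401	25587	3325	264	39644	1954	433	24885
D. mojavensis	213411	71191	36205	9772	311	49328	8516	755	35128
D. persimilis	306714	95957	103767	20144	856	130685	15423	1042	76465
D. pseudoobscura	266278	66505	20625	5603	298	54530	3265	379	19349
D. sechellia	214673	37740	17547	2840	300	34525	1420	538	18117
D. simulans	145544	39508	40197	5008	349	54565	3051	475	40803
D. triauraria	373410	171450	843725	79228	3461	812711	68228	5745	865396
D. virilis	211137	71644	19972	5503	265	48459	4207	757	20272
D. willistoni	332107	110725	382209	64535	2770	388208	59316	5193	405046
D. yakuba	283296	92344	28566	4248	424	59967	1839	687	27336
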