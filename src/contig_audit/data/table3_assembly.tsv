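species	est_genome_size_mb	ref_version	ref_size_mb	ref_n_scaffolds	ref_scaffold_n50_mb	ref_n_gt_100kb	ref_n_gt_1mb	asm_size_mb	asm_n_contigs	asm_contig_n50_mb	asm_n_gt_100kb	asm_n_gt_1mb
D. ananassae	196.6	1.05	231.0	13749	4.6	100	29	188.6	371	2.6	147	44
D. biarmipes	195.6	2.0	169.4	5523	3.4	95	32	184.6	666	2.8	224	32
D. bipectinata	204.6	2.0	167.3	5500	0.7	124	35	160.5	570	0.6	354	26
D. erecta	158.9	1.05	152.7	5124	18.7	38	8	127.7	58	16.6	29	21
D. eugracilis	228.9	2.0	156.9	4946	1.0	150	38	156.4	547	1.0	256	42
D. mauritiana	157.9	1.0	117.7	16	21.1	12	7	131.9	272	4.7	64	28
D. mojavensis	166.3	1.04	193.8	6841	24.8	51	12	162.1	122	5.0	86	39
D. persimilis	197.1	1.3	188.4	12838	1.9	142	30	165.7	415	3.5	146	35
D. pseudoobscura	167.7	3.04	152.7	4790	12.5	25	13	160.5	361	3.0	143	33
D. sechellia	166.7	1.3	166.6	14730	2.1	101	23	133.4	109	7.4	59	23
D. simulans	159.6	2.02	125.0	7619	23.5	8	6	132.2	76	7.7	61	24
D. triauraria	210.2	n/a	n/a	n/a	n/a	n/a	n/a	170.5	482	0.72	339	34
D. virilis	325.4	1.06	206.0	13530	10.2	79	22	165.9	141	4.1	83	40
D. willistoni	205.4	1.05	235.5	14838	4.5	80	38	197.7	490	1.5	270	49
D. yakuba	170.7	1.05	165.7	8122	21.8	60	8	141.1	111	5.2	68	32
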