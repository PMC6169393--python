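species	n_gapped_scaffolds	n_contigs_in_gapped	n_gaps	n_closed	pct_closed
D. ananassae	2305	9088	6783	3264	48
D. biarmipes	1258	3816	2558	1506	59
D. bipectinata	1639	4996	3357	1624	48
D. erecta	1064	3550	2486	1190	48
D. eugracilis	1153	4628	3475	1768	51
D. mauritiana	15	12459	12444	10726	86
D. mojavensis	1401	6434	5033	3300	66
D. persimilis	1636	15611	13975	11464	82
D. pseudoobscura	956	5551	4595	2298	50
D. sechellia	1558	8253	6695	5431	81
D. simulans	994	4599	3605	2572	71
D. virilis	1101	5953	4852	3242	67
D. willistoni	1728	7248	5520	1862	34
D. yakuba	1162	6562	5400	3704	69
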