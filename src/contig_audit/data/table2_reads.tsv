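species	depth_all	depth_gt_1kb	depth_gt_10kb	n_reads	mean_length	n_reads_gt_1kb	mean_length_gt_1kb	n_reads_gt_10kb	mean_length_gt_10kb	longest_read
D. ananassae	44.8	42.9	20.1	2085829	4227	1409289	5990	252071	15690	110391
D. biarmipes	28.8	27.5	12.9	1375651	4102	861668	6232	166579	15155	101492
D. bipectinata	22.6	20.5	9.9	1590181	2909	716348	5861	109688	18473	279705
D. erecta	31.7	30.6	17.5	1022546	4924	658736	7373	151078	18358	176712
D. eugracilis	22.5	21.2	8.2	1424426	3617	905481	5369	117316	15923	152351
D. mauritiana	32.6	32.1	17.1	852775	6045	717219	7066	175669	15402	93106
D. mojavensis	45.4	44.0	23.5	1471959	5129	1063822	6871	189302	20659	245241
D. persimilis	34.5	33.6	15.5	1386759	4910	1072290	6179	199330	15304	113218
D. pseudoobscura	33.3	31.7	13.8	1417469	3936	905571	5868	154234	15000	104401
D. sechellia	23.9	23.8	16.9	390359	10200	366174	10828	110941	25347	254031
D. simulans	30.2	30.0	25.1	389278	12393	311889	15346	140196	28532	309608
D. triauraria	18.8	18.7	13.1	409756	9634	379831	10338	120668	22876	238837
D. virilis	22.2	21.8	11.9	1209939	5969	1017016	6976	189572	20402	282795
D. willistoni	28.5	26.2	12.9	1868768	3132	923706	5816	158505	16757	100073
D. yakuba	21.7	21.5	12.6	509806	7277	462732	7947	103820	20699	195439
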