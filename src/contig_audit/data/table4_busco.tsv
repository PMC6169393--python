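species	published	miniasm	racon_x1	racon_x4	pilon_x1	pilon_x6	racon3_pilon3
D. ananassae	98.2	1.3	88.3	91.6	74.7	91.8	98.2
D. biarmipes	98.6	3.8	88.3	92	77.1	94.7	98.7
D. bipectinata	98.2	1.7	74.9	80.1	67.2	87.9	93.9
D. erecta	98.6	2.5	89.9	90.4	79.5	95.5	98.6
D. eugracilis	98.5	0.8	82.6	86.7	70.7	92.7	97.9
D. mauritiana	98.6	1.4	91	94.6	75.9	95	98.7
D. mojavensis	98.2	0.5	82.5	88.7	66.9	93.5	98
D. persimilis	96.6	0.4	80.3	85.3	62.1	90.9	98
D. pseudoobscura	97.0	1.7	84.1	88.8	72.3	93.9	98
D. sechellia	97.2	1.5	91.3	92.1	75.3	95.2	98.7
D. simulans	98.6	2.7	91.3	95.6	77.5	94.4	98.6
D. triauraria	n/a	3.1	82.9	85.0	73.5	87.9	93.8
D. virilis	97.5	1.1	84.9	89.3	70.9	93.6	97.7
D. willistoni	98.4	0.6	79.7	82.8	72.2	92.1	98.1
D. yakuba	98.5	1.3	86.7	91.2	73.7	95.5	98.4
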