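chromosome	total_snps	insertions	deletions	intergenic_noncoding	utr3	utr5	cds	synonymous	non_synonymous
1	207659	9689	11551	37325	3315	3488	22401	9024	13377
2	174855	8136	9504	30976	2654	2598	18779	7217	11562
3	160882	7727	8897	28632	2524	2583	16287	6222	10065
4	125653	5513	6447	23141	1732	2016	16142	6302	9840
5	124752	5852	6579	20269	1791	1800	13617	5302	8315
6	138429	5939	7031	24814	1611	1572	16234	6222	10012
7	139709	6048	7006	23905	1996	1841	16690	6492	10198
8	120056	5223	6106	20683	1593	1726	14161	5432	8729
9	109797	4761	5482	20000	1214	1363	12955	4882	8073
10	123407	5039	5875	20766	1434	1388	15048	5723	9325
11	134853	5637	6202	24649	1421	1431	18649	7043	11606
12	114308	4730	5396	19351	1401	1436	14135	5401	8734
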