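step	material_cost_per_sample	total_material_cost	labour_cost_per_sample	time_per_sample	total_time	total_cost
Size-sorting	—	—	15.09	0:15:00	453:45:00	27383.81
Homogenization	0.21	379.90	11.50	0:11:26	345:45:00	21252.45
Sample lysis	1.54	2795.64	1.91	0:01:54	57:37:30	6264.26
DNA extraction	1.02	1845.55	1.09	0:01:05	33:00:00	3823.27
QA DNA extraction	0.04	78.48	0.74	0:00:44	22:00:00	1417.24
1st PCR	1.65	2994.43	0.25	0:00:15	7:20:00	3450.83
PCR clean-up	0.50	898.46	0.74	0:00:44	22:00:00	2237.22
2nd PCR	1.65	2994.43	0.37	0:00:22	11:00:00	3663.81
Normalization	0.47	844.47	0.74	0:00:44	22:00:00	2183.23
Pooling	<0.01	0.45	0.13	0:00:08	4:00:00	243.86
QC libraries	<0.01	10.86	0.13	0:00:08	4:00:00	254.27
Sequencing	4.85	8800.00	—	—	—	8800.00
Bioinformatic analysis	—	—	1.59	0:01:35	48:00:00	2890.51
Instrument depreciation and maintenance	—	—	—	—	—	4000.00
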