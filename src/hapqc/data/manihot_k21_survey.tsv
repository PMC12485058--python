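genome	r_percent	s_percent	observed_percent	assembly_size_mb	haploid_size_mb	reported_maximum_percent	reported_expected_percent
Hanatee	1.50	92.9603	72.8236	545.8		78.65	73.12
HighlandRough	1.31	94.0010	73.1022	559.8		80.50	75.67
HighlandSmooth	1.37	94.1543	71.9676	553.4		79.94	75.27
Kasetsart50	1.41	94.5032	75.1543	587.1		79.52	75.15
Rayong9	1.25	94.0100	72.7629	552.1		81.16	76.30
Rayong72	1.51	94.0525	73.9351	594.5		78.52	73.85
Rayong90	1.34	94.9195	77.2268	668.5		80.22	76.14
WhiteRoot	1.39	94.6117	74.1047	570.5		79.73	75.43
WildType	4.56	96.3812	89.7580	1299.6	659	61.65	59.42
YellowRoot	1.47	94.0869	73.8572	593.5		78.95	74.28
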