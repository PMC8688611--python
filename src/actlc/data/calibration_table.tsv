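measured_pct	time_h	expected_pct	lower_pct	upper_pct
0	0.5	1	0	23
0	2	2	0	14
0	3.5	2	0	12
0	5	4	1	17
0	6.5	5	0	39
10	0.5	3	0	33
10	2	4	1	23
10	3.5	5	1	19
10	5	7	2	26
10	6.5	10	1	48
20	0.5	6	1	45
20	2	8	2	34
20	3.5	11	3	30
20	5	14	4	37
20	6.5	17	3	58
30	0.5	14	2	58
30	2	17	5	48
30	3.5	21	8	43
30	5	24	9	51
30	6.5	29	7	68
40	0.5	29	7	70
40	2	32	12	62
40	3.5	36	18	58
40	5	40	20	64
40	6.5	44	16	76
50	0.5	50	19	80
50	2	52	29	75
50	3.5	55	36	72
50	5	58	37	76
50	6.5	60	31	84
60	0.5	71	43	89
60	2	72	53	85
60	3.5	73	58	84
60	5	74	57	86
60	6.5	75	50	90
70	0.5	85	68	94
70	2	85	74	92
70	3.5	85	76	91
70	5	85	74	92
70	6.5	85	68	94
80	0.5	93	84	98
80	2	93	87	97
80	3.5	93	87	96
80	5	92	85	96
80	6.5	92	80	97
90	0.5	97	92	99
90	2	97	93	99
90	3.5	97	93	98
90	5	96	92	98
90	6.5	96	88	99
91	0.5	97	92	99
91	2	97	93	99
91	3.5	97	94	98
91	5	96	92	98
91	6.5	96	88	99
92	0.5	98	92	99
92	2	97	94	99
92	3.5	97	94	98
92	5	97	93	98
92	6.5	96	89	99
93	0.5	98	93	99
93	2	98	94	99
93	3.5	97	94	99
93	5	97	93	99
93	6.5	96	89	99
94	0.5	98	93	99
94	2	98	95	99
94	3.5	97	95	99
94	5	97	93	99
94	6.5	97	90	99
95	0.5	98	94	100
95	2	98	95	99
95	3.5	98	95	99
95	5	97	94	99
95	6.5	97	90	99
96	0.5	98	94	100
96	2	98	95	99
96	3.5	98	95	99
96	5	97	94	99
96	6.5	97	90	99
97	0.5	98	94	100
97	2	98	95	99
97	3.5	98	96	99
97	5	98	94	99
97	6.5	97	91	99
98	0.5	99	95	100
98	2	98	96	99
98	3.5	98	96	99
98	5	98	95	99
98	6.5	97	91	99
99	0.5	99	95	100
99	2	99	96	99
99	3.5	98	96	99
99	5	98	95	99
99	6.5	98	92	99
100	0.5	99	95	100
100	2	99	96	100
100	3.5	98	96	99
100	5	98	95	99
100	6.5	98	92	99
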