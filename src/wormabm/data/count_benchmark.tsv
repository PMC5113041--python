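sample_point	sim_time	obs_time	sim_count	obs_count
5	5	5	4	4
11	11	11	6	7
16	16	16	8	8
20	20	20	8	8
25	25	25	12	12
31	31	31	14	15
35	35	35	15	15
41	41	41	24	24
45	45	45	24	24
49	49	49	24	26
55	55	55	26	28
60	60	60	28	28
68	68	68	44	44
76	76	76	47	51
81	81	81	51	52
85	85	85	51	55
89	89	89	54	55
97	97	97	87	88
100	100	100	87	88
104	104	104	87	92
112	112	112	96	97
115	115	115	99	97
120	120	120	103	100
124	124.2464	124.2027	107	111
132	132.3937	132.576	154	162
140	140.541	140.9492	176	179
146	146.6515	146.5313	185	187
152	152.762	152.1134	188	189
157	157	157	190	190
160	160	160	191	190
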