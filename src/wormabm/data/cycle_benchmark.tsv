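name	sim_born	sim_divided	obs_born	obs_born_sd	obs_divided	obs_divided_sd
ABala	2504	3604	2508	36	3546	102
ABalp	2504	3503	2508	36	3540	102
ABara	2488	3498	2514	36	3546	102
ABarp	2488	3492	2514	36	3540	90
ABpla	2522	3578	2514	48	3522	96
ABplp	2522	3582	2514	48	3552	96
ABpra	2501	3534	2520	42	3540	96
ABprp	2501	3627	2520	42	3582	108
MS	1860	2979	1860	36	2928	84
E	1860	2948	1860	36	2994	84
C	2094	3241	2094	48	3198	108
P3	2094	3736	2094	48	3630	132
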