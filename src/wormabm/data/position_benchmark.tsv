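name	sim_x	sim_y	sim_z	obs_x	obs_y	obs_z	dev_x	dev_y	dev_z
ABala	-10.3181	-1.4295	2.156	-10.3185	-1.4285	2.1545	0.0004	0.001	0.0015
ABalp	-5.4404	6.4491	0.0724	-5.4435	6.4475	0.074	0.0031	0.0016	0.0016
ABara	-4.5968	-3.0929	4.6138	-4.596	-3.094	4.613	0.0008	0.0011	0.0008
ABarp	-0.6491	-5.1982	-2.2607	-0.649	-5.1985	-2.2605	0.0001	0.0003	0.0002
ABpla	-7.3182	-1.9064	-3.9134	-7.3145	-1.9025	-3.9135	0.0037	0.0039	0.0001
ABplp	1.2492	4.8501	-3.5957	1.2485	4.85	-3.5955	0.0007	0.0001	0.0002
ABpra	3.2836	-5.9391	2.2794	3.2845	-5.939	2.2795	0.0009	0.0001	0.0001
ABprp	8.8367	0.8474	2.6359	8.836	0.8445	2.636	0.0007	0.0029	0.0001
MS	-0.0008	0.004	-0.0022	0	0	0	0.0008	0.004	0.0022
E	9.1584	3.5893	-0.31	9.1555	3.5895	-0.3095	0.0029	0.0002	0.0005
C	5.1186	-2.3211	-3.7254	5.1119	-2.321	-3.725	0.0004	0.0001	0.0004
P3	12.252	3.723	0.1905	12.252	3.723	0.1905	0	0	0
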