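S003:r000000	bact|f000	86.64	227	0	0	0	0	0	0	1e-20	393.4	250
S003:r000001	bact|f000	90.12	212	0	0	0	0	0	0	1e-20	382.1	250
S003:r000002	bact|f000	92.48	233	0	0	0	0	0	0	1e-20	430.9	250
S003:r000003	bact|f000	86.96	240	0	0	0	0	0	0	1e-20	417.4	250
S003:r000004	bact|f000	87.83	205	0	0	0	0	0	0	1e-20	360.1	250
S003:r000005	bact|f000	94.91	231	0	0	0	0	0	0	1e-20	438.5	250
S003:r000006	bact|f000	90.67	220	0	0	0	0	0	0	1e-20	399.0	250
S003:r000007	bact|f000	94.18	238	0	0	0	0	0	0	1e-20	448.3	250
S003:r000010	bact|f003	93.62	247	0	0	0	0	0	0	1e-20	462.5	250
S003:r000012	bact|f003	89.92	243	0	0	0	0	0	0	1e-20	437.0	250
S003:r000014	bact|f004	94.83	226	0	0	0	0	0	0	1e-20	428.6	250
S003:r000015	bact|f004	86.42	230	0	0	0	0	0	0	1e-20	397.5	250
S003:r000016	bact|f004	86.40	207	0	0	0	0	0	0	1e-20	357.7	250
S003:r000017	bact|f004	97.59	248	0	0	0	0	0	0	1e-20	484.1	250
S003:r000018	bact|f005	90.43	206	0	0	0	0	0	0	1e-20	372.6	250
S003:r000019	bact|f005	94.93	213	0	0	0	0	0	0	1e-20	404.4	250
S003:r000020	bact|f005	92.34	189	0	0	0	0	0	0	1e-20	349.0	250
S003:r000021	bact|f006	94.45	225	0	0	0	0	0	0	1e-20	425.0	250
S003:r000022	bact|f006	86.03	225	0	0	0	0	0	0	1e-20	387.1	250
S003:r000023	bact|f006	91.41	231	0	0	0	0	0	0	1e-20	422.3	250
S003:r000024	bact|f006	96.00	226	0	0	0	0	0	0	1e-20	433.9	250
S003:r000025	bact|f006	97.06	185	0	0	0	0	0	0	1e-20	359.1	250
S003:r000026	bact|f006	86.94	239	0	0	0	0	0	0	1e-20	415.6	250
S003:r000027	bact|f006	91.73	217	0	0	0	0	0	0	1e-20	398.1	250
S003:r000028	bact|f006	93.47	240	0	0	0	0	0	0	1e-20	448.7	250
S003:r000029	bact|f006	96.38	232	0	0	0	0	0	0	1e-20	447.2	250
S003:r000030	bact|f006	94.23	216	0	0	0	0	0	0	1e-20	407.1	250
S003:r000031	bact|f006	97.06	233	0	0	0	0	0	0	1e-20	452.3	250
S003:r000032	bact|f006	98.46	221	0	0	0	0	0	0	1e-20	435.2	250
S003:r000033	bact|f006	89.94	245	0	0	0	0	0	0	1e-20	440.7	250
S003:r000034	bact|f008	89.79	221	0	0	0	0	0	0	1e-20	396.9	250
S003:r000035	bact|f008	93.80	222	0	0	0	0	0	0	1e-20	416.5	250
S003:r000036	bact|f009	92.36	223	0	0	0	0	0	0	1e-20	411.9	250
S003:r000037	bact|f010	97.89	211	0	0	0	0	0	0	1e-20	413.1	250
S003:r000038	bact|f010	93.09	228	0	0	0	0	0	0	1e-20	424.5	250
S003:r000039	bact|f010	86.22	231	0	0	0	0	0	0	1e-20	398.3	250
S003:b00000	bact|background	93.81	236	0	0	0	0	0	0	1e-20	442.8	250
S003:b00001	bact|background	90.81	223	0	0	0	0	0	0	1e-20	405.0	250
S003:b00002	bact|background	89.37	240	0	0	0	0	0	0	1e-20	429.0	250
S003:b00003	bact|background	91.12	242	0	0	0	0	0	0	1e-20	441.0	250
S003:b00004	bact|background	95.15	219	0	0	0	0	0	0	1e-20	416.8	250
S003:b00005	bact|background	88.06	226	0	0	0	0	0	0	1e-20	398.0	250
S003:b00006	bact|background	94.44	232	0	0	0	0	0	0	1e-20	438.2	250
S003:b00007	bact|background	88.20	237	0	0	0	0	0	0	1e-20	418.1	250
S003:b00008	bact|background	96.78	226	0	0	0	0	0	0	1e-20	437.5	250
S003:b00009	bact|background	98.74	243	0	0	0	0	0	0	1e-20	479.9	250
S003:b00010	bact|background	95.88	201	0	0	0	0	0	0	1e-20	385.4	250
S003:b00011	bact|background	95.31	224	0	0	0	0	0	0	1e-20	427.0	250
S003:b00012	bact|background	96.63	226	0	0	0	0	0	0	1e-20	436.8	250
S003:b00013	bact|background	86.76	237	0	0	0	0	0	0	1e-20	411.2	250
S003:b00014	bact|background	86.81	241	0	0	0	0	0	0	1e-20	418.4	250
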