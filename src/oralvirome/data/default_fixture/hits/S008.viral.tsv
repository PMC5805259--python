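S008:r000000	ref|f000s01	91.86	229	0	0	0	0	0	0	2.31e-12	420.7	250
S008:r000001	ref|f000s01	94.35	228	0	0	0	0	0	0	2.82e-22	430.3	250
S008:r000002	ref|f000s01	89.26	242	0	0	0	0	0	0	6.87e-24	432.0	250
S008:r000003	ref|f000s01	93.94	240	0	0	0	0	0	0	1.88e-19	450.9	250
S008:r000004	ref|f000s01	86.52	200	0	0	0	0	0	0	2.38e-27	346.1	250
S008:r000005	ref|f000s01	95.02	212	0	0	0	0	0	0	4.7e-07	402.9	250
S008:r000006	ref|f000s01	95.78	229	0	0	0	0	0	0	2.65e-25	438.7	250
S008:r000007	ref|f000s01	90.37	233	0	0	0	0	0	0	9.46e-19	421.1	250
S008:r000008	ref|f000s03	97.73	211	0	0	0	0	0	0	2e-20	412.4	250
S008:r000009	ref|f000s03	54.15	232	0	0	0	0	0	0	9.61e-23	251.3	250
S008:r000010	ref|f000s03	94.82	212	0	0	0	0	0	0	2.39e-26	402.0	250
S008:r000011	ref|f000s03	93.31	217	0	0	0	0	0	0	2.19e-13	405.0	250
S008:r000012	ref|f002s01	88.34	240	0	0	0	0	0	0	7.74e-27	424.0	250
S008:r000013	ref|f003s00	92.36	218	0	0	0	0	0	0	9.18e-21	402.7	250
S008:r000014	ref|f003s02	100.00	242	0	0	0	0	0	0	8.61e-18	484.0	250
S008:r000015	ref|f006s03	100.00	204	0	0	0	0	0	0	1.01e-29	408.0	250
S008:r000016	ref|f006s03	94.83	217	0	0	0	0	0	0	3.47e-09	411.6	250
S008:r000017	ref|f006s03	95.26	234	0	0	0	0	0	0	7.74e-19	445.8	250
S008:r000018	ref|f006s03	91.93	239	0	0	0	0	0	0	3.1e-18	439.4	250
S008:r000019	ref|f006s03	91.25	242	0	0	0	0	0	0	1.34e-30	441.7	250
S008:r000020	ref|f006s03	92.76	235	0	0	0	0	0	0	1.22e-07	436.0	250
S008:r000021	ref|f006s03	91.03	227	0	0	0	0	0	0	3.62e-07	413.3	250
S008:r000022	ref|f006s03	96.01	224	0	0	0	0	0	0	3.79e-05	430.1	250
S008:r000023	ref|f006s03	95.47	221	0	0	0	0	0	0	1.14e-25	422.0	250
S008:r000024	ref|f006s03	91.38	238	0	0	0	0	0	0	2.74e-27	435.0	250
S008:r000025	ref|f006s03	93.33	222	0	0	0	0	0	0	3.96e-29	414.4	250
S008:r000026	ref|f006s03	93.54	245	0	0	0	0	0	0	5.71e-23	458.4	250
S008:r000027	ref|f006s03	90.73	231	0	0	0	0	0	0	3.79e-05	419.2	250
S008:r000028	ref|f006s03	100.00	208	0	0	0	0	0	0	1.22e-24	416.0	250
S008:r000029	ref|f006s03	92.99	196	0	0	0	0	0	0	9.61e-26	364.5	250
S008:r000030	ref|f006s03	100.00	222	0	0	0	0	0	0	3.27e-22	444.0	250
S008:r000031	ref|f006s03	92.42	242	0	0	0	0	0	0	1.27e-27	447.3	250
S008:r000032	ref|f008s00	100.00	178	0	0	0	0	0	0	2.92e-07	356.0	250
S008:r000033	ref|f008s03	98.01	241	0	0	0	0	0	0	1.07e-06	472.4	250
S008:r000034	ref|f008s03	99.58	210	0	0	0	0	0	0	1.79e-13	418.2	250
S008:r000035	ref|f009s03	94.01	218	0	0	0	0	0	0	1.34e-24	409.9	250
S008:r000036	ref|f009s03	100.00	237	0	0	0	0	0	0	1.36e-10	474.0	250
S008:r000037	ref|f010s02	92.08	201	0	0	0	0	0	0	2.05e-09	370.2	250
S008:r000038	ref|f010s02	97.61	215	0	0	0	0	0	0	5.68e-21	419.7	250
S008:r000039	ref|f011s03	98.81	235	0	0	0	0	0	0	2.7e-23	464.4	250
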