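S005:r000000	ref|f000s01	100.00	241	0	0	0	0	0	0	5.02e-26	482.0	250
S005:r000001	ref|f000s01	91.12	232	0	0	0	0	0	0	7.8e-11	422.8	250
S005:r000002	ref|f000s01	100.00	224	0	0	0	0	0	0	9.73e-11	448.0	250
S005:r000003	ref|f000s01	96.93	216	0	0	0	0	0	0	3.47e-15	418.7	250
S005:r000004	ref|f000s01	92.99	248	0	0	0	0	0	0	2.49e-29	461.2	250
S005:r000005	ref|f000s03	99.06	238	0	0	0	0	0	0	8.56e-12	471.5	250
S005:r000006	ref|f000s03	93.50	237	0	0	0	0	0	0	3.53e-12	443.2	250
S005:r000007	ref|f000s03	91.33	243	0	0	0	0	0	0	6.07e-09	443.8	250
S005:r000008	ref|f000s03	96.22	216	0	0	0	0	0	0	2.39e-09	415.7	250
S005:r000009	ref|f000s03	88.70	226	0	0	0	0	0	0	6.52e-22	400.9	250
S005:r000010	ref|f000s03	92.23	206	0	0	0	0	0	0	2.87e-23	380.0	250
S005:r000011	ref|f000s03	93.59	236	0	0	0	0	0	0	7.51e-08	441.7	250
S005:r000012	ref|f000s03	100.00	230	0	0	0	0	0	0	3.59e-18	460.0	250
S005:r000013	ref|f000s03	92.08	237	0	0	0	0	0	0	1.04e-26	436.5	250
S005:r000014	ref|f000s03	99.54	245	0	0	0	0	0	0	3.45e-21	487.7	250
S005:r000015	ref|f001s03	97.55	213	0	0	0	0	0	0	4.03e-28	415.6	250
S005:r000016	ref|f003s02	99.71	235	0	0	0	0	0	0	4.16e-14	468.6	250
S005:r000017	ref|f003s02	96.65	212	0	0	0	0	0	0	1.3e-23	409.8	250
S005:r000017	ref|f003s00	96.65	212	0	0	0	0	0	0	1.3e-23	409.3	250
S005:r000018	ref|f003s02	100.00	227	0	0	0	0	0	0	3.59e-13	454.0	250
S005:r000019	ref|f005s02	91.03	245	0	0	0	0	0	0	1.35e-17	446.1	250
S005:r000020	ref|f005s02	99.36	242	0	0	0	0	0	0	1.12e-10	480.9	250
S005:r000021	ref|f005s02	99.02	225	0	0	0	0	0	0	1.62e-27	445.6	250
S005:r000022	ref|f005s02	91.91	191	0	0	0	0	0	0	5e-13	351.1	250
S005:r000023	ref|f005s02	88.66	231	0	0	0	0	0	0	4.09e-24	409.6	250
S005:r000024	ref|f005s02	85.19	214	0	0	0	0	0	0	3.07e-24	364.6	250
S005:r000025	ref|f005s02	96.79	230	0	0	0	0	0	0	8.98e-26	445.3	250
S005:r000026	ref|f005s02	91.51	249	0	0	0	0	0	0	6.34e-17	455.7	250
S005:r000027	ref|f005s02	91.82	229	0	0	0	0	0	0	3.07e-21	420.6	250
S005:r000028	ref|f005s02	100.00	225	0	0	0	0	0	0	1.05e-26	450.0	250
S005:r000029	ref|f005s02	93.90	238	0	0	0	0	0	0	1.05e-24	447.0	250
S005:r000030	ref|f006s03	99.58	231	0	0	0	0	0	0	5.63e-13	460.1	250
S005:r000031	ref|f006s03	100.00	210	0	0	0	0	0	0	1.77e-10	420.0	250
S005:r000032	ref|f006s03	92.36	201	0	0	0	0	0	0	7.14e-17	371.3	250
S005:r000033	ref|f006s03	93.18	244	0	0	0	0	0	0	9.25e-19	454.7	250
S005:r000034	ref|f006s03	93.44	227	0	0	0	0	0	0	8.17e-07	424.2	250
S005:r000035	ref|f007s02	85.79	218	0	0	0	0	0	0	4.75e-15	374.1	250
S005:r000036	ref|f008s03	99.55	217	0	0	0	0	0	0	3.4e-13	432.1	250
S005:r000037	ref|f008s03	92.44	243	0	0	0	0	0	0	2.5e-14	449.2	250
S005:r000038	ref|f008s03	92.31	225	0	0	0	0	0	0	8.76e-15	415.4	250
S005:r000039	ref|f009s03	100.00	228	0	0	0	0	0	0	3.25e-11	456.0	250
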