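S009:r000000	ref|f000s01	97.69	238	0	0	0	0	0	0	8.22e-27	465.0	250
S009:r000001	ref|f000s01	94.56	220	0	0	0	0	0	0	3.25e-07	416.0	250
S009:r000002	ref|f000s01	99.96	201	0	0	0	0	0	0	1.8e-09	401.9	250
S009:r000003	ref|f000s01	89.45	239	0	0	0	0	0	0	6.65e-07	427.6	250
S009:r000004	ref|f000s01	91.41	222	0	0	0	0	0	0	5.1e-30	405.9	250
S009:r000004	ref|f000s03	91.41	222	0	0	0	0	0	0	5.1e-30	405.4	250
S009:r000005	ref|f000s01	97.32	234	0	0	0	0	0	0	1.44e-14	455.4	250
S009:r000006	ref|f000s01	95.33	224	0	0	0	0	0	0	2.4e-09	427.1	250
S009:r000007	ref|f000s01	90.98	226	0	0	0	0	0	0	2.74e-18	411.2	250
S009:r000008	ref|f000s01	90.02	223	0	0	0	0	0	0	4.13e-21	401.5	250
S009:r000009	ref|f000s01	90.01	241	0	0	0	0	0	0	8.12e-15	433.9	250
S009:r000010	ref|f000s01	92.82	228	0	0	0	0	0	0	9.99e-09	423.2	250
S009:r000011	ref|f000s01	96.65	238	0	0	0	0	0	0	2.02e-14	460.0	250
S009:r000012	ref|f000s03	93.58	237	0	0	0	0	0	0	5.14e-17	443.6	250
S009:r000013	ref|f000s03	97.64	240	0	0	0	0	0	0	6.18e-20	468.7	250
S009:r000014	ref|f000s03	94.44	235	0	0	0	0	0	0	1.69e-09	443.9	250
S009:r000015	ref|f000s03	89.20	239	0	0	0	0	0	0	1.48e-05	426.4	250
S009:r000016	ref|f000s03	87.79	240	0	0	0	0	0	0	3.68e-13	421.4	250
S009:r000017	ref|f000s03	94.69	229	0	0	0	0	0	0	2.63e-08	433.7	250
S009:r000018	ref|f000s03	98.61	226	0	0	0	0	0	0	4.54e-23	445.7	250
S009:r000019	ref|f000s03	93.74	230	0	0	0	0	0	0	5.26e-12	431.2	250
S009:r000020	ref|f003s02	92.25	227	0	0	0	0	0	0	1.75e-06	418.8	250
S009:r000021	ref|f004s00	100.00	227	0	0	0	0	0	0	3.12e-06	454.0	250
S009:r000022	ref|f004s00	100.00	227	0	0	0	0	0	0	5.64e-26	454.0	250
S009:r000023	ref|f005s01	94.43	236	0	0	0	0	0	0	8.01e-16	445.7	250
S009:r000024	ref|f005s01	92.55	234	0	0	0	0	0	0	6.28e-09	433.1	250
S009:r000025	ref|f005s01	96.96	225	0	0	0	0	0	0	2.12e-22	436.3	250
S009:r000026	ref|f005s01	96.42	245	0	0	0	0	0	0	4.13e-10	472.5	250
S009:r000027	ref|f005s01	92.45	242	0	0	0	0	0	0	4.41e-18	447.5	250
S009:r000028	ref|f005s01	98.26	234	0	0	0	0	0	0	7.68e-08	459.9	250
S009:r000028	ref|f005s03	98.26	234	0	0	0	0	0	0	7.68e-08	459.4	250
S009:r000029	ref|f005s01	92.23	233	0	0	0	0	0	0	6.5e-10	429.8	250
S009:r000030	ref|f005s02	96.51	240	0	0	0	0	0	0	2.84e-28	463.3	250
S009:r000030	ref|f005s00	96.51	240	0	0	0	0	0	0	2.84e-28	462.8	250
S009:r000031	ref|f005s02	98.52	244	0	0	0	0	0	0	1.89e-10	480.8	250
S009:r000032	ref|f005s02	97.78	244	0	0	0	0	0	0	3.27e-22	477.2	250
S009:r000033	ref|f005s02	91.65	231	0	0	0	0	0	0	6.59e-07	423.4	250
S009:r000034	ref|f005s02	91.94	205	0	0	0	0	0	0	2.95e-12	376.9	250
S009:r000035	ref|f006s01	88.94	235	0	0	0	0	0	0	3.71e-17	418.0	250
S009:r000036	ref|f006s03	91.30	230	0	0	0	0	0	0	6.97e-23	420.0	250
S009:r000037	ref|f006s03	95.29	239	0	0	0	0	0	0	6.49e-17	455.5	250
S009:r000038	ref|f006s03	97.42	237	0	0	0	0	0	0	4.37e-22	461.8	250
S009:r000039	ref|f011s03	92.88	209	0	0	0	0	0	0	7.73e-30	388.2	250
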