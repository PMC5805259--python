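S003:r000000	ref|f000s03	97.51	207	0	0	0	0	0	0	2.76e-28	403.7	250
S003:r000001	ref|f000s03	91.39	229	0	0	0	0	0	0	1.07e-23	418.6	250
S003:r000002	ref|f000s03	100.00	205	0	0	0	0	0	0	2.18e-14	410.0	250
S003:r000003	ref|f000s03	100.00	246	0	0	0	0	0	0	4.24e-10	492.0	250
S003:r000004	ref|f000s03	91.66	235	0	0	0	0	0	0	1.17e-19	430.8	250
S003:r000005	ref|f000s03	100.00	210	0	0	0	0	0	0	1.19e-29	420.0	250
S003:r000006	ref|f000s03	94.63	228	0	0	0	0	0	0	1.54e-18	431.5	250
S003:r000007	ref|f000s03	100.00	244	0	0	0	0	0	0	8.97e-23	488.0	250
S003:r000008	ref|f003s00	91.71	205	0	0	0	0	0	0	4.18e-13	376.0	250
S003:r000009	ref|f003s02	100.00	247	0	0	0	0	0	0	2.06e-12	494.0	250
S003:r000010	ref|f003s02	91.10	230	0	0	0	0	0	0	4.51e-24	419.1	250
S003:r000011	ref|f003s02	93.52	214	0	0	0	0	0	0	4.69e-28	400.3	250
S003:r000012	ref|f003s02	100.00	220	0	0	0	0	0	0	3.35e-14	440.0	250
S003:r000013	ref|f003s03	98.99	206	0	0	0	0	0	0	1.33e-05	407.8	250
S003:r000014	ref|f004s00	95.87	247	0	0	0	0	0	0	3.85e-13	473.6	250
S003:r000015	ref|f004s00	97.23	247	0	0	0	0	0	0	9.76e-13	480.3	250
S003:r000015	ref|f004s02	97.23	247	0	0	0	0	0	0	9.76e-13	479.8	250
S003:r000016	ref|f004s00	93.80	222	0	0	0	0	0	0	5.21e-13	416.5	250
S003:r000016	ref|f004s02	93.80	222	0	0	0	0	0	0	5.21e-13	416.0	250
S003:r000017	ref|f004s00	95.00	226	0	0	0	0	0	0	6.96e-29	429.4	250
S003:r000018	ref|f005s01	94.56	212	0	0	0	0	0	0	1.12e-12	400.9	250
S003:r000019	ref|f005s02	90.57	228	0	0	0	0	0	0	3.46e-23	413.0	250
S003:r000020	ref|f005s02	90.07	233	0	0	0	0	0	0	5.08e-14	419.7	250
S003:r000021	ref|f006s03	87.61	169	0	0	0	0	0	0	6.33e-05	296.1	250
S003:r000022	ref|f006s03	94.02	242	0	0	0	0	0	0	1.64e-27	455.0	250
S003:r000023	ref|f006s03	99.77	211	0	0	0	0	0	0	6.66e-09	421.0	250
S003:r000024	ref|f006s03	97.76	220	0	0	0	0	0	0	2.99e-17	430.1	250
S003:r000025	ref|f006s03	91.58	219	0	0	0	0	0	0	1.43e-12	401.1	250
S003:r000026	ref|f006s03	83.51	200	0	0	0	0	0	0	3.15e-14	334.1	250
S003:r000027	ref|f006s03	96.97	230	0	0	0	0	0	0	2.41e-07	446.0	250
S003:r000028	ref|f006s03	94.73	240	0	0	0	0	0	0	2.03e-20	454.7	250
S003:r000029	ref|f006s03	95.58	237	0	0	0	0	0	0	5.72e-16	453.0	250
S003:r000030	ref|f006s03	94.19	233	0	0	0	0	0	0	1.1e-25	438.9	250
S003:r000031	ref|f006s03	96.92	235	0	0	0	0	0	0	6.17e-22	455.5	250
S003:r000032	ref|f006s03	100.00	205	0	0	0	0	0	0	4.67e-11	410.0	250
S003:r000033	ref|f006s03	94.40	240	0	0	0	0	0	0	3.89e-15	453.1	250
S003:r000034	ref|f008s03	99.70	229	0	0	0	0	0	0	5.29e-24	456.6	250
S003:r000035	ref|f008s03	95.79	216	0	0	0	0	0	0	2.18e-12	413.8	250
S003:r000036	ref|f009s03	92.03	223	0	0	0	0	0	0	2.15e-05	410.4	250
S003:r000037	ref|f010s01	90.10	213	0	0	0	0	0	0	3.35e-21	383.8	250
S003:r000038	ref|f010s01	96.35	234	0	0	0	0	0	0	1.58e-14	450.9	250
S003:r000039	ref|f010s03	96.81	234	0	0	0	0	0	0	9.6e-20	453.1	250
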