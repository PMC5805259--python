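S006:r000000	ref|f000s01	90.86	237	0	0	0	0	0	0	4.37e-28	430.7	250
S006:r000001	ref|f000s01	97.89	232	0	0	0	0	0	0	5.06e-22	454.2	250
S006:r000002	ref|f000s03	100.00	231	0	0	0	0	0	0	5.31e-17	462.0	250
S006:r000003	ref|f000s03	100.00	206	0	0	0	0	0	0	1.37e-13	412.0	250
S006:r000004	ref|f000s03	87.84	225	0	0	0	0	0	0	1.55e-06	395.3	250
S006:r000005	ref|f000s03	96.69	235	0	0	0	0	0	0	2.16e-10	454.4	250
S006:r000006	ref|f000s03	90.97	219	0	0	0	0	0	0	6.24e-24	398.4	250
S006:r000007	ref|f000s03	92.79	236	0	0	0	0	0	0	1.42e-26	438.0	250
S006:r000008	ref|f000s03	89.95	207	0	0	0	0	0	0	1.12e-24	372.4	250
S006:r000008	ref|f000s01	89.95	207	0	0	0	0	0	0	1.12e-24	371.9	250
S006:r000009	ref|f000s03	95.23	235	0	0	0	0	0	0	1.39e-23	447.6	250
S006:r000010	ref|f000s03	97.64	244	0	0	0	0	0	0	1.49e-12	476.5	250
S006:r000011	ref|f000s03	100.00	232	0	0	0	0	0	0	1.58e-25	464.0	250
S006:r000012	ref|f000s03	92.50	218	0	0	0	0	0	0	8.58e-11	403.3	250
S006:r000013	ref|f000s03	99.48	237	0	0	0	0	0	0	1.14e-26	471.5	250
S006:r000014	ref|f000s03	87.90	226	0	0	0	0	0	0	2.05e-10	397.3	250
S006:r000015	ref|f000s03	97.72	219	0	0	0	0	0	0	2.29e-14	428.0	250
S006:r000016	ref|f000s03	95.17	220	0	0	0	0	0	0	5.14e-24	418.7	250
S006:r000017	ref|f003s00	100.00	214	0	0	0	0	0	0	1.37e-28	428.0	250
S006:r000018	ref|f003s00	90.56	211	0	0	0	0	0	0	1.07e-17	382.2	250
S006:r000019	ref|f003s00	97.30	226	0	0	0	0	0	0	1.06e-16	439.8	250
S006:r000020	ref|f003s00	94.66	183	0	0	0	0	0	0	1.65e-26	346.5	250
S006:r000021	ref|f003s00	100.00	197	0	0	0	0	0	0	7.65e-15	394.0	250
S006:r000022	ref|f005s00	94.53	228	0	0	0	0	0	0	4.41e-16	431.1	250
S006:r000023	ref|f005s00	97.72	200	0	0	0	0	0	0	2.6e-26	390.9	250
S006:r000024	ref|f005s00	97.87	231	0	0	0	0	0	0	1.13e-25	452.2	250
S006:r000025	ref|f005s00	100.00	242	0	0	0	0	0	0	8.01e-24	484.0	250
S006:r000026	ref|f005s00	100.00	221	0	0	0	0	0	0	4.85e-08	442.0	250
S006:r000027	ref|f005s02	90.96	218	0	0	0	0	0	0	4.27e-08	396.6	250
S006:r000028	ref|f005s02	93.97	231	0	0	0	0	0	0	1.6e-20	434.1	250
S006:r000029	ref|f006s03	98.86	238	0	0	0	0	0	0	1.15e-08	470.6	250
S006:r000030	ref|f006s03	98.35	200	0	0	0	0	0	0	1.81e-05	393.4	250
S006:r000031	ref|f006s03	99.03	246	0	0	0	0	0	0	1.55e-17	487.2	250
S006:r000032	ref|f006s03	92.26	232	0	0	0	0	0	0	5.78e-07	428.1	250
S006:r000033	ref|f006s03	90.66	228	0	0	0	0	0	0	2.19e-18	413.4	250
S006:r000034	ref|f008s00	95.13	240	0	0	0	0	0	0	2.61e-28	456.6	250
S006:r000034	ref|f008s02	95.13	240	0	0	0	0	0	0	2.61e-28	456.1	250
S006:r000035	ref|f008s03	100.00	224	0	0	0	0	0	0	6.33e-12	448.0	250
S006:r000036	ref|f008s03	90.05	231	0	0	0	0	0	0	9.67e-20	416.0	250
S006:r000037	ref|f008s03	92.26	243	0	0	0	0	0	0	8.52e-21	448.4	250
S006:r000038	ref|f008s03	90.73	211	0	0	0	0	0	0	6.55e-27	382.9	250
S006:r000039	ref|f008s03	97.21	233	0	0	0	0	0	0	2.47e-24	453.0	250
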