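S001:r000000	ref|f000s00	99.89	230	0	0	0	0	0	0	1.68e-09	459.5	250
S001:r000001	ref|f000s00	92.63	235	0	0	0	0	0	0	8.14e-30	435.4	250
S001:r000002	ref|f000s00	90.96	200	0	0	0	0	0	0	2.68e-14	363.8	250
S001:r000003	ref|f000s00	91.00	232	0	0	0	0	0	0	1.44e-26	422.2	250
S001:r000003	ref|f000s02	91.00	232	0	0	0	0	0	0	1.44e-26	421.7	250
S001:r000004	ref|f000s00	89.31	221	0	0	0	0	0	0	1.19e-15	394.8	250
S001:r000005	ref|f000s00	91.36	241	0	0	0	0	0	0	5.19e-29	440.4	250
S001:r000006	ref|f000s03	99.22	242	0	0	0	0	0	0	1.6e-26	480.2	250
S001:r000007	ref|f000s03	93.30	229	0	0	0	0	0	0	7.7e-19	427.3	250
S001:r000008	ref|f003s02	94.99	238	0	0	0	0	0	0	1.02e-12	452.2	250
S001:r000009	ref|f003s02	95.14	97	0	0	0	0	0	0	5.44e-17	184.6	250
S001:r000010	ref|f005s02	94.36	222	0	0	0	0	0	0	1.14e-07	419.0	250
S001:r000011	ref|f005s02	95.56	211	0	0	0	0	0	0	4.44e-25	403.2	250
S001:r000012	ref|f005s02	100.00	242	0	0	0	0	0	0	2.89e-15	484.0	250
S001:r000013	ref|f005s02	95.55	244	0	0	0	0	0	0	3.93e-09	466.3	250
S001:r000014	ref|f005s02	94.99	221	0	0	0	0	0	0	6.42e-27	419.9	250
S001:r000015	ref|f005s02	94.66	239	0	0	0	0	0	0	1.69e-16	452.5	250
S001:r000016	ref|f006s03	92.09	235	0	0	0	0	0	0	8.64e-07	432.8	250
S001:r000017	ref|f006s03	93.27	233	0	0	0	0	0	0	7.59e-10	434.6	250
S001:r000018	ref|f006s03	100.00	214	0	0	0	0	0	0	4.45e-27	428.0	250
S001:r000019	ref|f006s03	93.85	233	0	0	0	0	0	0	3.61e-09	437.4	250
S001:r000020	ref|f006s03	91.76	222	0	0	0	0	0	0	1.36e-08	407.4	250
S001:r000021	ref|f007s01	92.26	230	0	0	0	0	0	0	1.21e-16	424.4	250
S001:r000022	ref|f007s02	93.59	241	0	0	0	0	0	0	4.88e-19	451.1	250
S001:r000023	ref|f008s03	93.70	244	0	0	0	0	0	0	2.68e-19	457.3	250
S001:r000024	ref|f008s03	96.83	240	0	0	0	0	0	0	1.42e-30	464.8	250
S001:r000024	ref|f008s01	96.83	240	0	0	0	0	0	0	1.42e-30	464.3	250
S001:r000025	ref|f009s02	96.97	231	0	0	0	0	0	0	1.15e-13	448.0	250
S001:r000026	ref|f009s02	90.35	223	0	0	0	0	0	0	6.11e-19	403.0	250
S001:r000027	ref|f009s02	96.39	176	0	0	0	0	0	0	3.8e-07	339.3	250
S001:r000028	ref|f009s02	95.98	238	0	0	0	0	0	0	2.54e-09	456.9	250
S001:r000029	ref|f009s02	89.02	221	0	0	0	0	0	0	2.77e-25	393.5	250
S001:r000030	ref|f009s02	90.73	232	0	0	0	0	0	0	1.33e-24	421.0	250
S001:r000031	ref|f009s02	93.51	238	0	0	0	0	0	0	1.46e-20	445.1	250
S001:r000032	ref|f009s02	90.69	235	0	0	0	0	0	0	2.31e-17	426.2	250
S001:r000033	ref|f009s02	90.72	233	0	0	0	0	0	0	1.07e-17	422.8	250
S001:r000034	ref|f009s02	100.00	220	0	0	0	0	0	0	8.06e-20	440.0	250
S001:r000035	ref|f009s02	94.16	246	0	0	0	0	0	0	7.29e-12	463.3	250
S001:r000036	ref|f009s02	95.79	226	0	0	0	0	0	0	1.34e-22	433.0	250
S001:r000037	ref|f009s02	94.25	239	0	0	0	0	0	0	1.02e-18	450.5	250
S001:r000038	ref|f009s02	100.00	232	0	0	0	0	0	0	1.25e-15	464.0	250
S001:r000039	ref|f010s02	98.20	214	0	0	0	0	0	0	3.41e-26	420.3	250
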