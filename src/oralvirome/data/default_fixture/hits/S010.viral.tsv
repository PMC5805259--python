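S010:r000000	ref|f000s01	95.50	194	0	0	0	0	0	0	1.72e-27	370.5	250
S010:r000001	ref|f000s02	97.80	246	0	0	0	0	0	0	2.65e-11	481.2	250
S010:r000002	ref|f000s02	99.33	230	0	0	0	0	0	0	3.64e-22	456.9	250
S010:r000003	ref|f000s03	99.44	212	0	0	0	0	0	0	1.09e-06	421.6	250
S010:r000004	ref|f003s00	99.34	249	0	0	0	0	0	0	1.53e-24	494.7	250
S010:r000005	ref|f003s00	86.11	238	0	0	0	0	0	0	2.38e-28	409.9	250
S010:r000005	ref|f003s02	86.11	238	0	0	0	0	0	0	2.38e-28	409.4	250
S010:r000006	ref|f003s00	95.49	239	0	0	0	0	0	0	1.56e-26	456.4	250
S010:r000007	ref|f005s00	94.10	233	0	0	0	0	0	0	2.54e-12	438.5	250
S010:r000008	ref|f005s03	86.85	211	0	0	0	0	0	0	5.56e-29	366.5	250
S010:r000009	ref|f005s03	100.00	188	0	0	0	0	0	0	3.05e-18	376.0	250
S010:r000010	ref|f005s03	95.64	223	0	0	0	0	0	0	5.92e-24	426.5	250
S010:r000011	ref|f005s03	96.10	228	0	0	0	0	0	0	1e-06	438.2	250
S010:r000012	ref|f005s03	95.42	232	0	0	0	0	0	0	2.6e-18	442.8	250
S010:r000013	ref|f005s03	100.00	229	0	0	0	0	0	0	6.67e-16	458.0	250
S010:r000014	ref|f005s03	87.33	212	0	0	0	0	0	0	3.38e-15	370.3	250
S010:r000015	ref|f005s03	87.65	244	0	0	0	0	0	0	2.69e-23	427.7	250
S010:r000016	ref|f005s03	91.21	242	0	0	0	0	0	0	1.78e-05	441.4	250
S010:r000017	ref|f005s03	95.88	234	0	0	0	0	0	0	4.55e-16	448.7	250
S010:r000018	ref|f005s03	100.00	234	0	0	0	0	0	0	1.65e-11	468.0	250
S010:r000019	ref|f006s03	88.92	232	0	0	0	0	0	0	4.98e-19	412.6	250
S010:r000020	ref|f006s03	97.47	240	0	0	0	0	0	0	1.02e-17	467.8	250
S010:r000021	ref|f008s03	97.27	245	0	0	0	0	0	0	4.78e-22	476.6	250
S010:r000022	ref|f008s03	96.47	227	0	0	0	0	0	0	1.04e-09	438.0	250
S010:r000023	ref|f008s03	96.68	90	0	0	0	0	0	0	1.2e-20	174.0	250
S010:r000024	ref|f008s03	100.00	238	0	0	0	0	0	0	8.14e-09	476.0	250
S010:r000025	ref|f009s02	100.00	239	0	0	0	0	0	0	7.44e-23	478.0	250
S010:r000026	ref|f009s02	95.88	240	0	0	0	0	0	0	8.23e-07	460.2	250
S010:r000027	ref|f009s02	95.69	248	0	0	0	0	0	0	1.93e-13	474.6	250
S010:r000028	ref|f009s02	93.29	201	0	0	0	0	0	0	8.52e-22	375.0	250
S010:r000029	ref|f009s02	97.11	243	0	0	0	0	0	0	1.08e-15	471.9	250
S010:r000030	ref|f009s02	95.92	219	0	0	0	0	0	0	3.13e-05	420.1	250
S010:r000030	ref|f009s00	95.92	219	0	0	0	0	0	0	3.13e-05	419.6	250
S010:r000031	ref|f009s02	98.05	234	0	0	0	0	0	0	5.93e-09	458.9	250
S010:r000032	ref|f009s02	99.76	234	0	0	0	0	0	0	1.02e-24	466.9	250
S010:r000033	ref|f009s02	96.20	228	0	0	0	0	0	0	0.00364	438.7	250
S010:r000034	ref|f009s02	93.37	223	0	0	0	0	0	0	5.46e-28	416.4	250
S010:r000035	ref|f009s02	87.80	243	0	0	0	0	0	0	1.81e-24	426.7	250
S010:r000036	ref|f009s02	92.68	225	0	0	0	0	0	0	7.05e-23	417.1	250
S010:r000037	ref|f009s02	100.00	237	0	0	0	0	0	0	1.9e-30	474.0	250
S010:r000038	ref|f009s02	95.26	220	0	0	0	0	0	0	3.77e-19	419.1	250
S010:r000039	ref|f009s02	94.42	229	0	0	0	0	0	0	5.17e-30	432.4	250
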