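S004:r000000	ref|f000s01	98.72	216	0	0	0	0	0	0	1.08e-19	426.5	250
S004:r000001	ref|f000s01	97.98	210	0	0	0	0	0	0	2.13e-08	411.5	250
S004:r000001	ref|f000s03	97.98	210	0	0	0	0	0	0	2.13e-08	411.0	250
S004:r000002	ref|f000s01	96.46	243	0	0	0	0	0	0	8.07e-08	468.8	250
S004:r000003	ref|f000s01	96.29	237	0	0	0	0	0	0	3.24e-29	456.4	250
S004:r000004	ref|f000s01	96.36	232	0	0	0	0	0	0	2.2e-26	447.1	250
S004:r000005	ref|f000s02	100.00	247	0	0	0	0	0	0	5.73e-15	494.0	250
S004:r000006	ref|f003s00	96.29	210	0	0	0	0	0	0	1.32e-14	404.4	250
S004:r000007	ref|f003s00	94.77	240	0	0	0	0	0	0	2.06e-27	454.9	250
S004:r000008	ref|f003s00	93.70	220	0	0	0	0	0	0	2.51e-13	412.3	250
S004:r000009	ref|f003s00	97.15	223	0	0	0	0	0	0	3.44e-16	433.3	250
S004:r000010	ref|f005s00	98.75	231	0	0	0	0	0	0	2.71e-26	456.2	250
S004:r000010	ref|f005s02	98.75	231	0	0	0	0	0	0	2.71e-26	455.7	250
S004:r000011	ref|f005s00	93.26	237	0	0	0	0	0	0	5.56e-10	442.1	250
S004:r000011	ref|f005s02	93.26	237	0	0	0	0	0	0	5.56e-10	441.6	250
S004:r000012	ref|f005s02	94.91	236	0	0	0	0	0	0	2.35e-17	448.0	250
S004:r000013	ref|f005s02	92.45	229	0	0	0	0	0	0	1.3e-23	423.4	250
S004:r000014	ref|f005s02	91.23	244	0	0	0	0	0	0	1.61e-27	445.2	250
S004:r000015	ref|f005s02	97.97	240	0	0	0	0	0	0	2.08e-07	470.2	250
S004:r000016	ref|f005s02	94.75	238	0	0	0	0	0	0	5.83e-29	451.0	250
S004:r000017	ref|f005s02	99.54	234	0	0	0	0	0	0	8.43e-11	465.8	250
S004:r000018	ref|f005s02	95.10	239	0	0	0	0	0	0	6.4e-30	454.6	250
S004:r000019	ref|f005s02	91.40	203	0	0	0	0	0	0	4.23e-12	371.1	250
S004:r000020	ref|f005s02	100.00	223	0	0	0	0	0	0	2.61e-05	446.0	250
S004:r000021	ref|f005s02	98.50	234	0	0	0	0	0	0	1.48e-23	461.0	250
S004:r000022	ref|f005s02	91.01	239	0	0	0	0	0	0	7.75e-09	435.0	250
S004:r000023	ref|f005s02	91.05	228	0	0	0	0	0	0	5.37e-05	415.2	250
S004:r000024	ref|f005s02	89.77	217	0	0	0	0	0	0	5.57e-27	389.6	250
S004:r000025	ref|f005s02	92.60	246	0	0	0	0	0	0	6.11e-08	455.6	250
S004:r000026	ref|f005s02	97.79	218	0	0	0	0	0	0	2.78e-22	426.4	250
S004:r000027	ref|f005s02	94.24	232	0	0	0	0	0	0	5.02e-08	437.3	250
S004:r000028	ref|f005s02	94.69	209	0	0	0	0	0	0	3.5e-16	395.8	250
S004:r000029	ref|f005s02	94.70	212	0	0	0	0	0	0	4.21e-13	401.5	250
S004:r000030	ref|f005s03	95.15	223	0	0	0	0	0	0	2.57e-27	424.4	250
S004:r000031	ref|f006s03	91.85	230	0	0	0	0	0	0	0.00867	422.5	250
S004:r000032	ref|f006s03	91.51	219	0	0	0	0	0	0	7.38e-14	400.8	250
S004:r000033	ref|f006s03	91.15	234	0	0	0	0	0	0	5.48e-30	426.6	250
S004:r000034	ref|f007s03	97.36	217	0	0	0	0	0	0	8.94e-09	422.5	250
S004:r000035	ref|f007s03	86.62	205	0	0	0	0	0	0	4.22e-25	355.2	250
S004:r000036	ref|f008s03	92.72	230	0	0	0	0	0	0	3.25e-25	426.5	250
S004:r000037	ref|f008s03	96.10	223	0	0	0	0	0	0	2.29e-14	428.6	250
S004:r000038	ref|f010s02	99.80	222	0	0	0	0	0	0	4.69e-13	443.1	250
S004:r000039	ref|f011s01	87.63	198	0	0	0	0	0	0	1.19e-27	347.0	250
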