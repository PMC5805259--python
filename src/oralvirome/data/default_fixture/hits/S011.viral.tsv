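S011:r000000	ref|f000s01	93.37	240	0	0	0	0	0	0	7.24e-12	448.2	250
S011:r000001	ref|f000s01	100.00	233	0	0	0	0	0	0	9.1e-28	466.0	250
S011:r000002	ref|f000s01	100.00	248	0	0	0	0	0	0	1.06e-22	496.0	250
S011:r000003	ref|f000s03	91.98	217	0	0	0	0	0	0	4.49e-30	399.2	250
S011:r000004	ref|f003s02	98.49	217	0	0	0	0	0	0	3.34e-14	427.5	250
S011:r000005	ref|f003s02	100.00	232	0	0	0	0	0	0	3.91e-22	464.0	250
S011:r000006	ref|f004s00	90.89	204	0	0	0	0	0	0	2.56e-11	370.8	250
S011:r000007	ref|f006s03	93.04	207	0	0	0	0	0	0	1.26e-13	385.2	250
S011:r000008	ref|f006s03	93.06	208	0	0	0	0	0	0	2.65e-22	387.1	250
S011:r000009	ref|f006s03	99.65	195	0	0	0	0	0	0	2.36e-18	388.6	250
S011:r000010	ref|f006s03	92.36	205	0	0	0	0	0	0	3.96e-19	378.7	250
S011:r000011	ref|f008s03	96.65	242	0	0	0	0	0	0	1.53e-23	467.8	250
S011:r000012	ref|f008s03	94.82	228	0	0	0	0	0	0	1.78e-28	432.4	250
S011:r000012	ref|f008s01	94.82	228	0	0	0	0	0	0	1.78e-28	431.9	250
S011:r000013	ref|f008s03	94.96	218	0	0	0	0	0	0	3.95e-28	414.0	250
S011:r000013	ref|f008s01	94.96	218	0	0	0	0	0	0	3.95e-28	413.5	250
S011:r000014	ref|f008s03	96.49	239	0	0	0	0	0	0	3.19e-07	461.2	250
S011:r000015	ref|f008s03	92.15	210	0	0	0	0	0	0	4.64e-16	387.0	250
S011:r000016	ref|f008s03	91.06	238	0	0	0	0	0	0	1.41e-12	433.4	250
S011:r000017	ref|f008s03	99.51	219	0	0	0	0	0	0	2.13e-11	435.9	250
S011:r000018	ref|f008s03	98.72	213	0	0	0	0	0	0	1.29e-22	420.5	250
S011:r000019	ref|f008s03	85.82	239	0	0	0	0	0	0	9.1e-13	410.2	250
S011:r000020	ref|f008s03	90.15	226	0	0	0	0	0	0	2.67e-17	407.5	250
S011:r000021	ref|f008s03	91.39	229	0	0	0	0	0	0	3.12e-30	418.5	250
S011:r000022	ref|f008s03	93.19	234	0	0	0	0	0	0	1.34e-17	436.1	250
S011:r000023	ref|f008s03	96.30	245	0	0	0	0	0	0	7.65e-14	471.9	250
S011:r000024	ref|f008s03	95.65	231	0	0	0	0	0	0	2.19e-19	441.9	250
S011:r000024	ref|f008s01	95.65	231	0	0	0	0	0	0	2.19e-19	441.4	250
S011:r000025	ref|f008s03	95.59	221	0	0	0	0	0	0	4.04e-13	422.5	250
S011:r000026	ref|f008s03	97.02	234	0	0	0	0	0	0	1.98e-20	454.0	250
S011:r000027	ref|f008s03	96.37	207	0	0	0	0	0	0	7.78e-29	399.0	250
S011:r000028	ref|f008s03	95.06	241	0	0	0	0	0	0	1.14e-09	458.2	250
S011:r000029	ref|f008s03	92.75	200	0	0	0	0	0	0	1.16e-29	371.0	250
S011:r000029	ref|f008s01	92.75	200	0	0	0	0	0	0	1.16e-29	370.5	250
S011:r000030	ref|f008s03	95.11	247	0	0	0	0	0	0	1.79e-12	469.8	250
S011:r000031	ref|f008s03	100.00	243	0	0	0	0	0	0	8.66e-09	486.0	250
S011:r000032	ref|f008s03	98.98	223	0	0	0	0	0	0	2.91e-17	441.5	250
S011:r000033	ref|f008s03	92.33	235	0	0	0	0	0	0	3.81e-11	434.0	250
S011:r000034	ref|f008s03	95.07	79	0	0	0	0	0	0	2.94e-06	150.2	250
S011:r000035	ref|f008s03	93.60	228	0	0	0	0	0	0	1.03e-21	426.8	250
S011:r000036	ref|f008s03	92.89	228	0	0	0	0	0	0	3.62e-06	423.6	250
S011:r000037	ref|f008s03	91.47	245	0	0	0	0	0	0	5.7e-22	448.2	250
S011:r000038	ref|f008s03	94.97	218	0	0	0	0	0	0	6.51e-08	414.1	250
S011:r000039	ref|f009s00	94.63	231	0	0	0	0	0	0	1.56e-28	437.2	250
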