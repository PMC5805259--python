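S008:r000000	bact|f000	87.61	210	0	0	0	0	0	0	1e-20	368.0	250
S008:r000001	bact|f000	92.94	246	0	0	0	0	0	0	1e-20	457.3	250
S008:r000002	bact|f000	85.04	221	0	0	0	0	0	0	1e-20	375.9	250
S008:r000003	bact|f000	98.50	196	0	0	0	0	0	0	1e-20	386.1	250
S008:r000004	bact|f000	88.76	239	0	0	0	0	0	0	1e-20	424.3	250
S008:r000005	bact|f000	97.98	235	0	0	0	0	0	0	1e-20	460.5	250
S008:r000006	bact|f000	97.71	222	0	0	0	0	0	0	1e-20	433.9	250
S008:r000007	bact|f000	93.08	231	0	0	0	0	0	0	1e-20	430.0	250
S008:r000008	bact|f000	95.61	222	0	0	0	0	0	0	1e-20	424.5	250
S008:r000009	bact|f000	94.34	237	0	0	0	0	0	0	1e-20	447.2	250
S008:r000010	bact|f000	98.54	234	0	0	0	0	0	0	1e-20	461.2	250
S008:r000011	bact|f000	92.60	213	0	0	0	0	0	0	1e-20	394.5	250
S008:r000012	bact|f002	96.53	231	0	0	0	0	0	0	1e-20	446.0	250
S008:r000013	bact|f003	91.72	231	0	0	0	0	0	0	1e-20	423.8	250
S008:r000015	bact|f006	97.98	227	0	0	0	0	0	0	1e-20	444.8	250
S008:r000016	bact|f006	85.50	242	0	0	0	0	0	0	1e-20	413.8	250
S008:r000017	bact|f006	85.28	237	0	0	0	0	0	0	1e-20	404.2	250
S008:r000018	bact|f006	89.91	232	0	0	0	0	0	0	1e-20	417.2	250
S008:r000019	bact|f006	87.96	223	0	0	0	0	0	0	1e-20	392.3	250
S008:r000020	bact|f006	92.54	231	0	0	0	0	0	0	1e-20	427.5	250
S008:r000021	bact|f006	92.93	234	0	0	0	0	0	0	1e-20	434.9	250
S008:r000022	bact|f006	92.94	227	0	0	0	0	0	0	1e-20	421.9	250
S008:r000023	bact|f006	91.49	228	0	0	0	0	0	0	1e-20	417.2	250
S008:r000024	bact|f006	95.47	243	0	0	0	0	0	0	1e-20	464.0	250
S008:r000025	bact|f006	95.99	203	0	0	0	0	0	0	1e-20	389.7	250
S008:r000027	bact|f006	86.53	238	0	0	0	0	0	0	1e-20	411.9	250
S008:r000028	bact|f006	88.04	240	0	0	0	0	0	0	1e-20	422.6	250
S008:r000029	bact|f006	97.07	238	0	0	0	0	0	0	1e-20	462.0	250
S008:r000030	bact|f006	95.40	216	0	0	0	0	0	0	1e-20	412.1	250
S008:r000031	bact|f006	98.60	234	0	0	0	0	0	0	1e-20	461.4	250
S008:r000032	bact|f008	90.86	233	0	0	0	0	0	0	1e-20	423.4	250
S008:r000033	bact|f008	94.72	246	0	0	0	0	0	0	1e-20	466.0	250
S008:r000034	bact|f008	91.96	242	0	0	0	0	0	0	1e-20	445.1	250
S008:r000035	bact|f009	92.87	240	0	0	0	0	0	0	1e-20	445.8	250
S008:r000036	bact|f009	94.92	229	0	0	0	0	0	0	1e-20	434.7	250
S008:r000037	bact|f010	94.86	235	0	0	0	0	0	0	1e-20	445.8	250
S008:r000038	bact|f010	92.32	214	0	0	0	0	0	0	1e-20	395.1	250
S008:b00000	bact|background	86.39	210	0	0	0	0	0	0	1e-20	362.9	250
S008:b00001	bact|background	87.42	246	0	0	0	0	0	0	1e-20	430.1	250
S008:b00002	bact|background	85.58	178	0	0	0	0	0	0	1e-20	304.7	250
S008:b00003	bact|background	95.01	240	0	0	0	0	0	0	1e-20	456.0	250
S008:b00004	bact|background	97.93	245	0	0	0	0	0	0	1e-20	479.9	250
S008:b00005	bact|background	91.63	249	0	0	0	0	0	0	1e-20	456.3	250
S008:b00006	bact|background	93.27	200	0	0	0	0	0	0	1e-20	373.1	250
S008:b00007	bact|background	89.59	244	0	0	0	0	0	0	1e-20	437.2	250
S008:b00008	bact|background	92.38	221	0	0	0	0	0	0	1e-20	408.3	250
S008:b00009	bact|background	87.06	238	0	0	0	0	0	0	1e-20	414.4	250
S008:b00010	bact|background	90.44	238	0	0	0	0	0	0	1e-20	430.5	250
S008:b00011	bact|background	93.09	223	0	0	0	0	0	0	1e-20	415.2	250
S008:b00012	bact|background	86.66	247	0	0	0	0	0	0	1e-20	428.1	250
S008:b00013	bact|background	94.57	218	0	0	0	0	0	0	1e-20	412.3	250
S008:b00014	bact|background	87.69	227	0	0	0	0	0	0	1e-20	398.1	250
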