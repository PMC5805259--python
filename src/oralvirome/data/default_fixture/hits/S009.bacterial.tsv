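S009:r000002	bact|f000	89.40	201	0	0	0	0	0	0	1e-20	359.4	250
S009:r000003	bact|f000	87.10	228	0	0	0	0	0	0	1e-20	397.2	250
S009:r000004	bact|f000	91.98	218	0	0	0	0	0	0	1e-20	401.0	250
S009:r000005	bact|f000	94.61	226	0	0	0	0	0	0	1e-20	427.6	250
S009:r000006	bact|f000	91.25	228	0	0	0	0	0	0	1e-20	416.1	250
S009:r000007	bact|f000	95.68	245	0	0	0	0	0	0	1e-20	468.8	250
S009:r000008	bact|f000	89.09	196	0	0	0	0	0	0	1e-20	349.2	250
S009:r000009	bact|f000	92.55	234	0	0	0	0	0	0	1e-20	433.1	250
S009:r000010	bact|f000	93.57	225	0	0	0	0	0	0	1e-20	421.1	250
S009:r000011	bact|f000	93.52	203	0	0	0	0	0	0	1e-20	379.7	250
S009:r000012	bact|f000	89.59	246	0	0	0	0	0	0	1e-20	440.8	250
S009:r000013	bact|f000	94.60	230	0	0	0	0	0	0	1e-20	435.2	250
S009:r000014	bact|f000	98.71	231	0	0	0	0	0	0	1e-20	456.0	250
S009:r000015	bact|f000	91.19	220	0	0	0	0	0	0	1e-20	401.3	250
S009:r000016	bact|f000	96.78	238	0	0	0	0	0	0	1e-20	460.7	250
S009:r000017	bact|f000	96.88	222	0	0	0	0	0	0	1e-20	430.2	250
S009:r000018	bact|f000	98.72	233	0	0	0	0	0	0	1e-20	460.1	250
S009:r000019	bact|f000	87.71	209	0	0	0	0	0	0	1e-20	366.6	250
S009:r000020	bact|f003	89.75	214	0	0	0	0	0	0	1e-20	384.1	250
S009:r000021	bact|f004	92.25	209	0	0	0	0	0	0	1e-20	385.6	250
S009:r000022	bact|f004	96.79	240	0	0	0	0	0	0	1e-20	464.6	250
S009:r000023	bact|f005	91.18	235	0	0	0	0	0	0	1e-20	428.6	250
S009:r000024	bact|f005	90.44	208	0	0	0	0	0	0	1e-20	376.2	250
S009:r000025	bact|f005	86.95	247	0	0	0	0	0	0	1e-20	429.5	250
S009:r000026	bact|f005	91.87	209	0	0	0	0	0	0	1e-20	384.0	250
S009:r000027	bact|f005	89.47	236	0	0	0	0	0	0	1e-20	422.3	250
S009:r000028	bact|f005	86.55	224	0	0	0	0	0	0	1e-20	387.7	250
S009:r000029	bact|f005	86.33	240	0	0	0	0	0	0	1e-20	414.4	250
S009:r000030	bact|f005	92.66	243	0	0	0	0	0	0	1e-20	450.3	250
S009:r000031	bact|f005	91.84	221	0	0	0	0	0	0	1e-20	405.9	250
S009:r000032	bact|f005	88.51	227	0	0	0	0	0	0	1e-20	401.8	250
S009:r000033	bact|f005	92.01	229	0	0	0	0	0	0	1e-20	421.4	250
S009:r000034	bact|f005	97.84	209	0	0	0	0	0	0	1e-20	409.0	250
S009:r000035	bact|f006	86.34	227	0	0	0	0	0	0	1e-20	392.0	250
S009:r000036	bact|f006	97.63	215	0	0	0	0	0	0	1e-20	419.8	250
S009:r000037	bact|f006	88.33	185	0	0	0	0	0	0	1e-20	326.8	250
S009:r000038	bact|f006	96.88	231	0	0	0	0	0	0	1e-20	447.6	250
S009:b00000	bact|background	94.58	213	0	0	0	0	0	0	1e-20	402.9	250
S009:b00001	bact|background	96.91	219	0	0	0	0	0	0	1e-20	424.5	250
S009:b00002	bact|background	88.92	214	0	0	0	0	0	0	1e-20	380.6	250
S009:b00003	bact|background	90.28	238	0	0	0	0	0	0	1e-20	429.7	250
S009:b00004	bact|background	85.17	207	0	0	0	0	0	0	1e-20	352.6	250
S009:b00005	bact|background	97.49	234	0	0	0	0	0	0	1e-20	456.3	250
S009:b00006	bact|background	87.60	199	0	0	0	0	0	0	1e-20	348.7	250
S009:b00007	bact|background	93.66	228	0	0	0	0	0	0	1e-20	427.1	250
S009:b00008	bact|background	95.64	230	0	0	0	0	0	0	1e-20	439.9	250
S009:b00009	bact|background	97.58	235	0	0	0	0	0	0	1e-20	458.6	250
S009:b00010	bact|background	87.80	242	0	0	0	0	0	0	1e-20	425.0	250
S009:b00011	bact|background	97.53	229	0	0	0	0	0	0	1e-20	446.7	250
S009:b00012	bact|background	87.73	217	0	0	0	0	0	0	1e-20	380.8	250
S009:b00013	bact|background	89.16	197	0	0	0	0	0	0	1e-20	351.3	250
S009:b00014	bact|background	85.33	227	0	0	0	0	0	0	1e-20	387.4	250
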