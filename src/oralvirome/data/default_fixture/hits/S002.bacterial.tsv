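S002:r000001	bact|f000	85.04	242	0	0	0	0	0	0	1e-20	411.6	250
S002:r000002	bact|f000	98.64	231	0	0	0	0	0	0	1e-20	455.7	250
S002:r000003	bact|f000	95.50	236	0	0	0	0	0	0	1e-20	450.7	250
S002:r000004	bact|f000	88.39	232	0	0	0	0	0	0	1e-20	410.1	250
S002:r000005	bact|f000	93.27	232	0	0	0	0	0	0	1e-20	432.8	250
S002:r000006	bact|f000	94.59	245	0	0	0	0	0	0	1e-20	463.5	250
S002:r000008	bact|f000	86.28	232	0	0	0	0	0	0	1e-20	400.3	250
S002:r000009	bact|f000	89.79	206	0	0	0	0	0	0	1e-20	369.9	250
S002:r000010	bact|f000	98.67	242	0	0	0	0	0	0	1e-20	477.5	250
S002:r000011	bact|f000	89.38	235	0	0	0	0	0	0	1e-20	420.1	250
S002:r000012	bact|f000	98.96	219	0	0	0	0	0	0	1e-20	433.4	250
S002:r000013	bact|f003	91.53	206	0	0	0	0	0	0	1e-20	377.1	250
S002:r000014	bact|f003	87.53	223	0	0	0	0	0	0	1e-20	390.4	250
S002:r000016	bact|f005	90.25	229	0	0	0	0	0	0	1e-20	413.4	250
S002:r000017	bact|f008	96.26	234	0	0	0	0	0	0	1e-20	450.5	250
S002:r000018	bact|f008	98.42	236	0	0	0	0	0	0	1e-20	464.6	250
S002:r000019	bact|f008	98.97	220	0	0	0	0	0	0	1e-20	435.5	250
S002:r000020	bact|f008	92.15	233	0	0	0	0	0	0	1e-20	429.4	250
S002:r000021	bact|f008	87.71	180	0	0	0	0	0	0	1e-20	315.7	250
S002:r000022	bact|f008	95.42	229	0	0	0	0	0	0	1e-20	437.0	250
S002:r000023	bact|f008	97.18	237	0	0	0	0	0	0	1e-20	460.6	250
S002:r000024	bact|f008	88.57	193	0	0	0	0	0	0	1e-20	341.9	250
S002:r000025	bact|f008	94.41	223	0	0	0	0	0	0	1e-20	421.1	250
S002:r000026	bact|f008	89.18	216	0	0	0	0	0	0	1e-20	385.3	250
S002:r000027	bact|f008	90.94	199	0	0	0	0	0	0	1e-20	361.9	250
S002:r000028	bact|f008	90.57	230	0	0	0	0	0	0	1e-20	416.6	250
S002:r000029	bact|f008	91.95	213	0	0	0	0	0	0	1e-20	391.7	250
S002:r000030	bact|f008	89.97	235	0	0	0	0	0	0	1e-20	422.9	250
S002:r000031	bact|f008	85.22	246	0	0	0	0	0	0	1e-20	419.3	250
S002:r000032	bact|f008	90.06	235	0	0	0	0	0	0	1e-20	423.3	250
S002:r000033	bact|f008	94.35	217	0	0	0	0	0	0	1e-20	409.5	250
S002:r000034	bact|f008	95.74	220	0	0	0	0	0	0	1e-20	421.3	250
S002:r000035	bact|f008	94.34	237	0	0	0	0	0	0	1e-20	447.2	250
S002:r000036	bact|f010	97.35	236	0	0	0	0	0	0	1e-20	459.5	250
S002:r000037	bact|f010	89.89	178	0	0	0	0	0	0	1e-20	320.0	250
S002:r000038	bact|f010	89.56	229	0	0	0	0	0	0	1e-20	410.2	250
S002:r000039	bact|f010	92.50	234	0	0	0	0	0	0	1e-20	432.9	250
S002:b00000	bact|background	96.43	246	0	0	0	0	0	0	1e-20	474.4	250
S002:b00001	bact|background	86.44	235	0	0	0	0	0	0	1e-20	406.3	250
S002:b00002	bact|background	91.05	240	0	0	0	0	0	0	1e-20	437.0	250
S002:b00003	bact|background	91.02	226	0	0	0	0	0	0	1e-20	411.4	250
S002:b00004	bact|background	87.70	177	0	0	0	0	0	0	1e-20	310.4	250
S002:b00005	bact|background	88.09	217	0	0	0	0	0	0	1e-20	382.3	250
S002:b00006	bact|background	95.54	231	0	0	0	0	0	0	1e-20	441.4	250
S002:b00007	bact|background	88.26	230	0	0	0	0	0	0	1e-20	406.0	250
S002:b00008	bact|background	85.50	216	0	0	0	0	0	0	1e-20	369.4	250
S002:b00009	bact|background	98.18	217	0	0	0	0	0	0	1e-20	426.1	250
S002:b00010	bact|background	92.25	225	0	0	0	0	0	0	1e-20	415.1	250
S002:b00011	bact|background	87.37	218	0	0	0	0	0	0	1e-20	380.9	250
S002:b00012	bact|background	92.94	247	0	0	0	0	0	0	1e-20	459.1	250
S002:b00013	bact|background	85.18	231	0	0	0	0	0	0	1e-20	393.5	250
S002:b00014	bact|background	86.89	232	0	0	0	0	0	0	1e-20	403.2	250
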