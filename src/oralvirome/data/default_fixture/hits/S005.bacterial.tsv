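S005:r000000	bact|f000	85.25	211	0	0	0	0	0	0	1e-20	359.8	250
S005:r000002	bact|f000	85.34	231	0	0	0	0	0	0	1e-20	394.3	250
S005:r000003	bact|f000	88.00	233	0	0	0	0	0	0	1e-20	410.1	250
S005:r000004	bact|f000	95.74	231	0	0	0	0	0	0	1e-20	442.3	250
S005:r000005	bact|f000	94.55	217	0	0	0	0	0	0	1e-20	410.4	250
S005:r000006	bact|f000	87.11	248	0	0	0	0	0	0	1e-20	432.1	250
S005:r000007	bact|f000	91.75	224	0	0	0	0	0	0	1e-20	411.0	250
S005:r000008	bact|f000	88.36	197	0	0	0	0	0	0	1e-20	348.1	250
S005:r000009	bact|f000	87.45	208	0	0	0	0	0	0	1e-20	363.8	250
S005:r000010	bact|f000	85.91	243	0	0	0	0	0	0	1e-20	417.5	250
S005:r000011	bact|f000	87.25	235	0	0	0	0	0	0	1e-20	410.1	250
S005:r000012	bact|f000	87.51	226	0	0	0	0	0	0	1e-20	395.5	250
S005:r000013	bact|f000	93.47	235	0	0	0	0	0	0	1e-20	439.3	250
S005:r000014	bact|f000	87.83	221	0	0	0	0	0	0	1e-20	388.2	250
S005:r000016	bact|f003	87.85	241	0	0	0	0	0	0	1e-20	423.5	250
S005:r000017	bact|f003	86.28	221	0	0	0	0	0	0	1e-20	381.3	250
S005:r000019	bact|f005	87.70	228	0	0	0	0	0	0	1e-20	399.9	250
S005:r000020	bact|f005	87.24	233	0	0	0	0	0	0	1e-20	406.5	250
S005:r000021	bact|f005	85.67	235	0	0	0	0	0	0	1e-20	402.7	250
S005:r000022	bact|f005	96.55	241	0	0	0	0	0	0	1e-20	465.4	250
S005:r000023	bact|f005	94.12	207	0	0	0	0	0	0	1e-20	389.7	250
S005:r000024	bact|f005	91.93	219	0	0	0	0	0	0	1e-20	402.7	250
S005:r000025	bact|f005	93.95	209	0	0	0	0	0	0	1e-20	392.7	250
S005:r000026	bact|f005	93.79	234	0	0	0	0	0	0	1e-20	439.0	250
S005:r000027	bact|f005	97.62	227	0	0	0	0	0	0	1e-20	443.2	250
S005:r000028	bact|f005	88.65	242	0	0	0	0	0	0	1e-20	429.1	250
S005:r000029	bact|f005	93.05	188	0	0	0	0	0	0	1e-20	349.9	250
S005:r000030	bact|f006	88.14	226	0	0	0	0	0	0	1e-20	398.4	250
S005:r000031	bact|f006	95.75	217	0	0	0	0	0	0	1e-20	415.5	250
S005:r000032	bact|f006	98.13	197	0	0	0	0	0	0	1e-20	386.6	250
S005:r000033	bact|f006	98.30	236	0	0	0	0	0	0	1e-20	464.0	250
S005:r000034	bact|f006	91.69	175	0	0	0	0	0	0	1e-20	320.9	250
S005:r000035	bact|f007	94.69	201	0	0	0	0	0	0	1e-20	380.7	250
S005:r000036	bact|f008	96.29	238	0	0	0	0	0	0	1e-20	458.3	250
S005:r000037	bact|f008	96.62	208	0	0	0	0	0	0	1e-20	401.9	250
S005:r000038	bact|f008	90.10	247	0	0	0	0	0	0	1e-20	445.1	250
S005:r000039	bact|f009	87.30	241	0	0	0	0	0	0	1e-20	420.8	250
S005:b00000	bact|background	98.83	202	0	0	0	0	0	0	1e-20	399.3	250
S005:b00001	bact|background	85.36	232	0	0	0	0	0	0	1e-20	396.1	250
S005:b00002	bact|background	88.73	205	0	0	0	0	0	0	1e-20	363.8	250
S005:b00003	bact|background	92.86	218	0	0	0	0	0	0	1e-20	404.9	250
S005:b00004	bact|background	87.25	230	0	0	0	0	0	0	1e-20	401.4	250
S005:b00005	bact|background	98.74	231	0	0	0	0	0	0	1e-20	456.2	250
S005:b00006	bact|background	98.55	245	0	0	0	0	0	0	1e-20	482.9	250
S005:b00007	bact|background	87.10	224	0	0	0	0	0	0	1e-20	390.2	250
S005:b00008	bact|background	94.55	206	0	0	0	0	0	0	1e-20	389.5	250
S005:b00009	bact|background	88.18	223	0	0	0	0	0	0	1e-20	393.3	250
S005:b00010	bact|background	93.92	239	0	0	0	0	0	0	1e-20	449.0	250
S005:b00011	bact|background	93.09	240	0	0	0	0	0	0	1e-20	446.9	250
S005:b00012	bact|background	87.61	222	0	0	0	0	0	0	1e-20	389.0	250
S005:b00013	bact|background	93.79	230	0	0	0	0	0	0	1e-20	431.4	250
S005:b00014	bact|background	91.17	219	0	0	0	0	0	0	1e-20	399.3	250
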