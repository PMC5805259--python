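S010:r000000	bact|f000	95.68	234	0	0	0	0	0	0	1e-20	447.8	250
S010:r000001	bact|f000	92.01	241	0	0	0	0	0	0	1e-20	443.5	250
S010:r000003	bact|f000	96.26	199	0	0	0	0	0	0	1e-20	383.1	250
S010:r000004	bact|f003	92.98	238	0	0	0	0	0	0	1e-20	442.6	250
S010:r000005	bact|f003	87.73	233	0	0	0	0	0	0	1e-20	408.8	250
S010:r000007	bact|f005	93.43	207	0	0	0	0	0	0	1e-20	386.8	250
S010:r000008	bact|f005	95.54	220	0	0	0	0	0	0	1e-20	420.4	250
S010:r000009	bact|f005	87.91	202	0	0	0	0	0	0	1e-20	355.2	250
S010:r000010	bact|f005	96.03	212	0	0	0	0	0	0	1e-20	407.2	250
S010:r000011	bact|f005	94.34	236	0	0	0	0	0	0	1e-20	445.3	250
S010:r000012	bact|f005	94.89	242	0	0	0	0	0	0	1e-20	459.2	250
S010:r000013	bact|f005	91.27	184	0	0	0	0	0	0	1e-20	335.9	250
S010:r000014	bact|f005	91.75	226	0	0	0	0	0	0	1e-20	414.7	250
S010:r000015	bact|f005	91.60	199	0	0	0	0	0	0	1e-20	364.6	250
S010:r000016	bact|f005	87.36	222	0	0	0	0	0	0	1e-20	387.9	250
S010:r000017	bact|f005	92.80	232	0	0	0	0	0	0	1e-20	430.6	250
S010:r000018	bact|f005	87.38	231	0	0	0	0	0	0	1e-20	403.7	250
S010:r000020	bact|f006	97.71	237	0	0	0	0	0	0	1e-20	463.2	250
S010:r000021	bact|f008	96.75	228	0	0	0	0	0	0	1e-20	441.2	250
S010:r000022	bact|f008	86.08	244	0	0	0	0	0	0	1e-20	420.1	250
S010:r000023	bact|f008	87.10	248	0	0	0	0	0	0	1e-20	432.0	250
S010:r000024	bact|f008	96.60	215	0	0	0	0	0	0	1e-20	415.4	250
S010:r000025	bact|f009	94.53	182	0	0	0	0	0	0	1e-20	344.1	250
S010:r000026	bact|f009	98.65	238	0	0	0	0	0	0	1e-20	469.6	250
S010:r000027	bact|f009	95.31	238	0	0	0	0	0	0	1e-20	453.7	250
S010:r000028	bact|f009	88.66	244	0	0	0	0	0	0	1e-20	432.7	250
S010:r000029	bact|f009	95.43	225	0	0	0	0	0	0	1e-20	429.4	250
S010:r000030	bact|f009	86.43	236	0	0	0	0	0	0	1e-20	407.9	250
S010:r000031	bact|f009	90.36	240	0	0	0	0	0	0	1e-20	433.7	250
S010:r000032	bact|f009	93.05	240	0	0	0	0	0	0	1e-20	446.6	250
S010:r000033	bact|f009	94.31	243	0	0	0	0	0	0	1e-20	458.4	250
S010:r000034	bact|f009	93.61	221	0	0	0	0	0	0	1e-20	413.7	250
S010:r000035	bact|f009	96.22	223	0	0	0	0	0	0	1e-20	429.1	250
S010:r000036	bact|f009	97.41	235	0	0	0	0	0	0	1e-20	457.8	250
S010:r000037	bact|f009	88.60	220	0	0	0	0	0	0	1e-20	389.8	250
S010:r000038	bact|f009	87.09	228	0	0	0	0	0	0	1e-20	397.1	250
S010:r000039	bact|f009	96.08	233	0	0	0	0	0	0	1e-20	447.7	250
S010:b00000	bact|background	92.16	194	0	0	0	0	0	0	1e-20	357.6	250
S010:b00001	bact|background	93.87	234	0	0	0	0	0	0	1e-20	439.3	250
S010:b00002	bact|background	95.43	218	0	0	0	0	0	0	1e-20	416.1	250
S010:b00003	bact|background	85.49	231	0	0	0	0	0	0	1e-20	395.0	250
S010:b00004	bact|background	97.74	229	0	0	0	0	0	0	1e-20	447.6	250
S010:b00005	bact|background	88.06	229	0	0	0	0	0	0	1e-20	403.3	250
S010:b00006	bact|background	93.28	223	0	0	0	0	0	0	1e-20	416.0	250
S010:b00007	bact|background	91.42	222	0	0	0	0	0	0	1e-20	405.9	250
S010:b00008	bact|background	93.70	243	0	0	0	0	0	0	1e-20	455.4	250
S010:b00009	bact|background	93.46	212	0	0	0	0	0	0	1e-20	396.3	250
S010:b00010	bact|background	91.26	229	0	0	0	0	0	0	1e-20	418.0	250
S010:b00011	bact|background	89.36	219	0	0	0	0	0	0	1e-20	391.4	250
S010:b00012	bact|background	91.43	222	0	0	0	0	0	0	1e-20	406.0	250
S010:b00013	bact|background	97.67	231	0	0	0	0	0	0	1e-20	451.2	250
S010:b00014	bact|background	93.92	224	0	0	0	0	0	0	1e-20	420.8	250
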