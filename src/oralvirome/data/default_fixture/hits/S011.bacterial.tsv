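S011:r000000	bact|f000	90.39	245	0	0	0	0	0	0	1e-20	442.9	250
S011:r000001	bact|f000	92.22	238	0	0	0	0	0	0	1e-20	439.0	250
S011:r000002	bact|f000	87.18	242	0	0	0	0	0	0	1e-20	422.0	250
S011:r000003	bact|f000	90.00	228	0	0	0	0	0	0	1e-20	410.4	250
S011:r000006	bact|f004	97.18	198	0	0	0	0	0	0	1e-20	384.9	250
S011:r000008	bact|f006	98.49	235	0	0	0	0	0	0	1e-20	462.9	250
S011:r000009	bact|f006	89.81	213	0	0	0	0	0	0	1e-20	382.6	250
S011:r000010	bact|f006	89.91	230	0	0	0	0	0	0	1e-20	413.6	250
S011:r000011	bact|f008	93.78	224	0	0	0	0	0	0	1e-20	420.1	250
S011:r000012	bact|f008	86.48	186	0	0	0	0	0	0	1e-20	321.7	250
S011:r000013	bact|f008	90.56	222	0	0	0	0	0	0	1e-20	402.1	250
S011:r000014	bact|f008	88.89	226	0	0	0	0	0	0	1e-20	401.8	250
S011:r000015	bact|f008	97.73	216	0	0	0	0	0	0	1e-20	422.2	250
S011:r000016	bact|f008	93.05	232	0	0	0	0	0	0	1e-20	431.8	250
S011:r000017	bact|f008	93.41	207	0	0	0	0	0	0	1e-20	386.7	250
S011:r000018	bact|f008	89.42	230	0	0	0	0	0	0	1e-20	411.3	250
S011:r000019	bact|f008	88.24	191	0	0	0	0	0	0	1e-20	337.1	250
S011:r000020	bact|f008	94.47	180	0	0	0	0	0	0	1e-20	340.1	250
S011:r000021	bact|f008	92.72	224	0	0	0	0	0	0	1e-20	415.4	250
S011:r000022	bact|f008	98.62	239	0	0	0	0	0	0	1e-20	471.4	250
S011:r000023	bact|f008	89.55	226	0	0	0	0	0	0	1e-20	404.8	250
S011:r000024	bact|f008	90.89	242	0	0	0	0	0	0	1e-20	439.9	250
S011:r000025	bact|f008	98.67	226	0	0	0	0	0	0	1e-20	446.0	250
S011:r000026	bact|f008	96.85	233	0	0	0	0	0	0	1e-20	451.3	250
S011:r000027	bact|f008	96.27	211	0	0	0	0	0	0	1e-20	406.2	250
S011:r000028	bact|f008	87.74	213	0	0	0	0	0	0	1e-20	373.8	250
S011:r000029	bact|f008	87.81	217	0	0	0	0	0	0	1e-20	381.1	250
S011:r000030	bact|f008	89.31	235	0	0	0	0	0	0	1e-20	419.8	250
S011:r000031	bact|f008	88.71	218	0	0	0	0	0	0	1e-20	386.8	250
S011:r000032	bact|f008	91.57	242	0	0	0	0	0	0	1e-20	443.2	250
S011:r000033	bact|f008	94.43	177	0	0	0	0	0	0	1e-20	334.3	250
S011:r000034	bact|f008	97.84	214	0	0	0	0	0	0	1e-20	418.7	250
S011:r000035	bact|f008	98.34	234	0	0	0	0	0	0	1e-20	460.2	250
S011:r000036	bact|f008	92.54	231	0	0	0	0	0	0	1e-20	427.5	250
S011:r000037	bact|f008	85.58	237	0	0	0	0	0	0	1e-20	405.6	250
S011:r000038	bact|f008	96.69	210	0	0	0	0	0	0	1e-20	406.1	250
S011:r000039	bact|f009	93.75	244	0	0	0	0	0	0	1e-20	457.5	250
S011:b00000	bact|background	92.73	230	0	0	0	0	0	0	1e-20	426.5	250
S011:b00001	bact|background	86.50	245	0	0	0	0	0	0	1e-20	423.8	250
S011:b00002	bact|background	91.47	225	0	0	0	0	0	0	1e-20	411.6	250
S011:b00003	bact|background	92.05	230	0	0	0	0	0	0	1e-20	423.4	250
S011:b00004	bact|background	87.16	220	0	0	0	0	0	0	1e-20	383.5	250
S011:b00005	bact|background	93.80	241	0	0	0	0	0	0	1e-20	452.1	250
S011:b00006	bact|background	88.76	197	0	0	0	0	0	0	1e-20	349.7	250
S011:b00007	bact|background	94.19	240	0	0	0	0	0	0	1e-20	452.1	250
S011:b00008	bact|background	91.27	245	0	0	0	0	0	0	1e-20	447.2	250
S011:b00009	bact|background	87.62	207	0	0	0	0	0	0	1e-20	362.7	250
S011:b00010	bact|background	90.58	227	0	0	0	0	0	0	1e-20	411.2	250
S011:b00011	bact|background	89.67	226	0	0	0	0	0	0	1e-20	405.3	250
S011:b00012	bact|background	94.27	234	0	0	0	0	0	0	1e-20	441.2	250
S011:b00013	bact|background	87.32	238	0	0	0	0	0	0	1e-20	415.7	250
S011:b00014	bact|background	97.64	239	0	0	0	0	0	0	1e-20	466.7	250
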