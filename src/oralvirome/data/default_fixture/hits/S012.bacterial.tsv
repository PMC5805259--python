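S012:r000000	bact|f000	98.41	228	0	0	0	0	0	0	1e-20	448.7	250
S012:r000001	bact|f000	98.09	226	0	0	0	0	0	0	1e-20	443.4	250
S012:r000006	bact|f004	86.40	202	0	0	0	0	0	0	1e-20	349.1	250
S012:r000007	bact|f004	93.71	244	0	0	0	0	0	0	1e-20	457.3	250
S012:r000008	bact|f005	90.12	226	0	0	0	0	0	0	1e-20	407.3	250
S012:r000009	bact|f005	88.31	212	0	0	0	0	0	0	1e-20	374.4	250
S012:r000010	bact|f005	93.01	206	0	0	0	0	0	0	1e-20	383.2	250
S012:r000011	bact|f005	86.91	222	0	0	0	0	0	0	1e-20	385.9	250
S012:r000012	bact|f005	98.32	208	0	0	0	0	0	0	1e-20	409.0	250
S012:r000013	bact|f005	92.00	234	0	0	0	0	0	0	1e-20	430.6	250
S012:r000014	bact|f005	98.18	212	0	0	0	0	0	0	1e-20	416.3	250
S012:r000015	bact|f005	90.48	219	0	0	0	0	0	0	1e-20	396.3	250
S012:r000016	bact|f005	89.87	244	0	0	0	0	0	0	1e-20	438.6	250
S012:r000017	bact|f006	95.13	231	0	0	0	0	0	0	1e-20	439.5	250
S012:r000018	bact|f006	90.01	236	0	0	0	0	0	0	1e-20	424.8	250
S012:r000019	bact|f006	88.75	229	0	0	0	0	0	0	1e-20	406.5	250
S012:r000020	bact|f006	96.68	217	0	0	0	0	0	0	1e-20	419.6	250
S012:r000021	bact|f006	93.52	202	0	0	0	0	0	0	1e-20	377.8	250
S012:r000022	bact|f006	95.22	235	0	0	0	0	0	0	1e-20	447.5	250
S012:r000023	bact|f006	85.51	236	0	0	0	0	0	0	1e-20	403.6	250
S012:r000024	bact|f006	87.10	238	0	0	0	0	0	0	1e-20	414.6	250
S012:r000025	bact|f006	91.91	233	0	0	0	0	0	0	1e-20	428.3	250
S012:r000026	bact|f007	86.98	243	0	0	0	0	0	0	1e-20	422.7	250
S012:r000027	bact|f007	96.18	239	0	0	0	0	0	0	1e-20	459.7	250
S012:r000028	bact|f007	86.21	239	0	0	0	0	0	0	1e-20	412.1	250
S012:r000029	bact|f008	86.84	249	0	0	0	0	0	0	1e-20	432.5	250
S012:r000030	bact|f008	86.36	246	0	0	0	0	0	0	1e-20	424.9	250
S012:r000031	bact|f008	86.02	211	0	0	0	0	0	0	1e-20	363.0	250
S012:r000032	bact|f008	92.98	213	0	0	0	0	0	0	1e-20	396.1	250
S012:r000033	bact|f008	92.34	200	0	0	0	0	0	0	1e-20	369.4	250
S012:r000034	bact|f008	97.41	230	0	0	0	0	0	0	1e-20	448.1	250
S012:r000036	bact|f010	91.52	232	0	0	0	0	0	0	1e-20	424.6	250
S012:r000037	bact|f010	91.06	195	0	0	0	0	0	0	1e-20	355.1	250
S012:r000038	bact|f010	93.72	233	0	0	0	0	0	0	1e-20	436.7	250
S012:r000039	bact|f010	95.79	248	0	0	0	0	0	0	1e-20	475.1	250
S012:b00000	bact|background	85.13	209	0	0	0	0	0	0	1e-20	355.8	250
S012:b00001	bact|background	96.70	220	0	0	0	0	0	0	1e-20	425.5	250
S012:b00002	bact|background	92.05	237	0	0	0	0	0	0	1e-20	436.3	250
S012:b00003	bact|background	85.86	207	0	0	0	0	0	0	1e-20	355.5	250
S012:b00004	bact|background	95.14	211	0	0	0	0	0	0	1e-20	401.5	250
S012:b00005	bact|background	90.61	225	0	0	0	0	0	0	1e-20	407.7	250
S012:b00006	bact|background	90.52	219	0	0	0	0	0	0	1e-20	396.5	250
S012:b00007	bact|background	89.30	241	0	0	0	0	0	0	1e-20	430.4	250
S012:b00008	bact|background	96.87	238	0	0	0	0	0	0	1e-20	461.1	250
S012:b00009	bact|background	87.76	223	0	0	0	0	0	0	1e-20	391.4	250
S012:b00010	bact|background	94.04	244	0	0	0	0	0	0	1e-20	458.9	250
S012:b00011	bact|background	92.51	240	0	0	0	0	0	0	1e-20	444.1	250
S012:b00012	bact|background	93.98	236	0	0	0	0	0	0	1e-20	443.6	250
S012:b00013	bact|background	89.52	214	0	0	0	0	0	0	1e-20	383.1	250
S012:b00014	bact|background	88.36	236	0	0	0	0	0	0	1e-20	417.1	250
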