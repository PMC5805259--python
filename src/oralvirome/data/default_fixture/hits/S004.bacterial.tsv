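S004:r000000	bact|f000	98.78	221	0	0	0	0	0	0	1e-20	436.6	250
S004:r000001	bact|f000	91.56	235	0	0	0	0	0	0	1e-20	430.3	250
S004:r000002	bact|f000	97.06	237	0	0	0	0	0	0	1e-20	460.1	250
S004:r000003	bact|f000	86.89	241	0	0	0	0	0	0	1e-20	418.8	250
S004:r000004	bact|f000	86.41	230	0	0	0	0	0	0	1e-20	397.5	250
S004:r000005	bact|f000	90.07	244	0	0	0	0	0	0	1e-20	439.5	250
S004:r000006	bact|f003	91.88	201	0	0	0	0	0	0	1e-20	369.4	250
S004:r000009	bact|f003	94.00	249	0	0	0	0	0	0	1e-20	468.1	250
S004:r000010	bact|f005	86.26	236	0	0	0	0	0	0	1e-20	407.1	250
S004:r000011	bact|f005	85.85	216	0	0	0	0	0	0	1e-20	370.9	250
S004:r000012	bact|f005	87.11	213	0	0	0	0	0	0	1e-20	371.1	250
S004:r000013	bact|f005	96.09	234	0	0	0	0	0	0	1e-20	449.7	250
S004:r000014	bact|f005	89.66	217	0	0	0	0	0	0	1e-20	389.1	250
S004:r000015	bact|f005	95.16	231	0	0	0	0	0	0	1e-20	439.6	250
S004:r000016	bact|f005	88.31	243	0	0	0	0	0	0	1e-20	429.2	250
S004:r000017	bact|f005	86.95	224	0	0	0	0	0	0	1e-20	389.5	250
S004:r000018	bact|f005	86.32	208	0	0	0	0	0	0	1e-20	359.1	250
S004:r000020	bact|f005	92.31	190	0	0	0	0	0	0	1e-20	350.8	250
S004:r000021	bact|f005	90.72	232	0	0	0	0	0	0	1e-20	421.0	250
S004:r000022	bact|f005	98.77	199	0	0	0	0	0	0	1e-20	393.1	250
S004:r000023	bact|f005	92.81	217	0	0	0	0	0	0	1e-20	402.8	250
S004:r000024	bact|f005	88.83	163	0	0	0	0	0	0	1e-20	289.6	250
S004:r000025	bact|f005	94.13	227	0	0	0	0	0	0	1e-20	427.3	250
S004:r000026	bact|f005	86.37	234	0	0	0	0	0	0	1e-20	404.2	250
S004:r000027	bact|f005	95.09	238	0	0	0	0	0	0	1e-20	452.6	250
S004:r000028	bact|f005	97.34	209	0	0	0	0	0	0	1e-20	406.9	250
S004:r000029	bact|f005	92.73	243	0	0	0	0	0	0	1e-20	450.7	250
S004:r000030	bact|f005	92.92	215	0	0	0	0	0	0	1e-20	399.5	250
S004:r000031	bact|f006	98.71	236	0	0	0	0	0	0	1e-20	465.9	250
S004:r000033	bact|f006	96.32	226	0	0	0	0	0	0	1e-20	435.4	250
S004:r000034	bact|f007	87.78	231	0	0	0	0	0	0	1e-20	405.5	250
S004:r000035	bact|f007	90.59	206	0	0	0	0	0	0	1e-20	373.2	250
S004:r000036	bact|f008	95.79	231	0	0	0	0	0	0	1e-20	442.5	250
S004:r000038	bact|f010	87.71	210	0	0	0	0	0	0	1e-20	368.4	250
S004:b00000	bact|background	87.49	240	0	0	0	0	0	0	1e-20	419.9	250
S004:b00001	bact|background	91.37	236	0	0	0	0	0	0	1e-20	431.3	250
S004:b00002	bact|background	97.21	237	0	0	0	0	0	0	1e-20	460.8	250
S004:b00003	bact|background	90.88	241	0	0	0	0	0	0	1e-20	438.0	250
S004:b00004	bact|background	87.95	241	0	0	0	0	0	0	1e-20	423.9	250
S004:b00005	bact|background	93.07	240	0	0	0	0	0	0	1e-20	446.7	250
S004:b00006	bact|background	92.92	227	0	0	0	0	0	0	1e-20	421.9	250
S004:b00007	bact|background	86.16	239	0	0	0	0	0	0	1e-20	411.8	250
S004:b00008	bact|background	93.41	208	0	0	0	0	0	0	1e-20	388.6	250
S004:b00009	bact|background	95.08	228	0	0	0	0	0	0	1e-20	433.6	250
S004:b00010	bact|background	96.54	241	0	0	0	0	0	0	1e-20	465.3	250
S004:b00011	bact|background	97.24	224	0	0	0	0	0	0	1e-20	435.7	250
S004:b00012	bact|background	89.28	236	0	0	0	0	0	0	1e-20	421.4	250
S004:b00013	bact|background	91.57	216	0	0	0	0	0	0	1e-20	395.6	250
S004:b00014	bact|background	91.44	213	0	0	0	0	0	0	1e-20	389.5	250
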