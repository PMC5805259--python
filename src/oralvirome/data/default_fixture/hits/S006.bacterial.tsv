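S006:r000000	bact|f000	86.01	215	0	0	0	0	0	0	1e-20	369.9	250
S006:r000001	bact|f000	91.72	223	0	0	0	0	0	0	1e-20	409.1	250
S006:r000002	bact|f000	92.69	241	0	0	0	0	0	0	1e-20	446.8	250
S006:r000003	bact|f000	90.15	218	0	0	0	0	0	0	1e-20	393.1	250
S006:r000004	bact|f000	96.29	180	0	0	0	0	0	0	1e-20	346.7	250
S006:r000005	bact|f000	89.91	236	0	0	0	0	0	0	1e-20	424.4	250
S006:r000006	bact|f000	97.23	229	0	0	0	0	0	0	1e-20	445.3	250
S006:r000007	bact|f000	92.65	224	0	0	0	0	0	0	1e-20	415.1	250
S006:r000008	bact|f000	94.73	225	0	0	0	0	0	0	1e-20	426.3	250
S006:r000009	bact|f000	86.39	240	0	0	0	0	0	0	1e-20	414.7	250
S006:r000010	bact|f000	88.61	249	0	0	0	0	0	0	1e-20	441.3	250
S006:r000011	bact|f000	85.78	233	0	0	0	0	0	0	1e-20	399.7	250
S006:r000012	bact|f000	96.44	241	0	0	0	0	0	0	1e-20	464.8	250
S006:r000013	bact|f000	95.10	220	0	0	0	0	0	0	1e-20	418.4	250
S006:r000014	bact|f000	94.50	226	0	0	0	0	0	0	1e-20	427.1	250
S006:r000015	bact|f000	86.03	248	0	0	0	0	0	0	1e-20	426.7	250
S006:r000016	bact|f000	91.30	233	0	0	0	0	0	0	1e-20	425.5	250
S006:r000022	bact|f005	94.24	243	0	0	0	0	0	0	1e-20	458.0	250
S006:r000023	bact|f005	96.22	208	0	0	0	0	0	0	1e-20	400.3	250
S006:r000024	bact|f005	90.00	227	0	0	0	0	0	0	1e-20	408.6	250
S006:r000025	bact|f005	97.64	209	0	0	0	0	0	0	1e-20	408.1	250
S006:r000027	bact|f005	87.19	236	0	0	0	0	0	0	1e-20	411.5	250
S006:r000028	bact|f005	85.52	245	0	0	0	0	0	0	1e-20	419.1	250
S006:r000029	bact|f006	87.58	220	0	0	0	0	0	0	1e-20	385.4	250
S006:r000030	bact|f006	96.27	225	0	0	0	0	0	0	1e-20	433.2	250
S006:r000031	bact|f006	92.22	167	0	0	0	0	0	0	1e-20	308.0	250
S006:r000032	bact|f006	92.57	244	0	0	0	0	0	0	1e-20	451.7	250
S006:r000033	bact|f006	92.10	238	0	0	0	0	0	0	1e-20	438.4	250
S006:r000034	bact|f008	91.27	218	0	0	0	0	0	0	1e-20	397.9	250
S006:r000035	bact|f008	97.21	219	0	0	0	0	0	0	1e-20	425.8	250
S006:r000036	bact|f008	87.59	206	0	0	0	0	0	0	1e-20	360.9	250
S006:r000037	bact|f008	93.09	204	0	0	0	0	0	0	1e-20	379.8	250
S006:r000038	bact|f008	86.12	210	0	0	0	0	0	0	1e-20	361.7	250
S006:r000039	bact|f008	97.08	233	0	0	0	0	0	0	1e-20	452.4	250
S006:b00000	bact|background	85.69	234	0	0	0	0	0	0	1e-20	401.0	250
S006:b00001	bact|background	93.12	216	0	0	0	0	0	0	1e-20	402.3	250
S006:b00002	bact|background	94.10	246	0	0	0	0	0	0	1e-20	463.0	250
S006:b00003	bact|background	91.19	245	0	0	0	0	0	0	1e-20	446.8	250
S006:b00004	bact|background	89.22	238	0	0	0	0	0	0	1e-20	424.7	250
S006:b00005	bact|background	91.91	177	0	0	0	0	0	0	1e-20	325.4	250
S006:b00006	bact|background	92.49	223	0	0	0	0	0	0	1e-20	412.5	250
S006:b00007	bact|background	89.36	234	0	0	0	0	0	0	1e-20	418.2	250
S006:b00008	bact|background	92.30	186	0	0	0	0	0	0	1e-20	343.3	250
S006:b00009	bact|background	94.42	226	0	0	0	0	0	0	1e-20	426.8	250
S006:b00010	bact|background	93.10	221	0	0	0	0	0	0	1e-20	411.5	250
S006:b00011	bact|background	98.80	222	0	0	0	0	0	0	1e-20	438.7	250
S006:b00012	bact|background	95.73	238	0	0	0	0	0	0	1e-20	455.7	250
S006:b00013	bact|background	93.19	239	0	0	0	0	0	0	1e-20	445.4	250
S006:b00014	bact|background	85.39	234	0	0	0	0	0	0	1e-20	399.6	250
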