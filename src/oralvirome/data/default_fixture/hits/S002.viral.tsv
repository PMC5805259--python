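S002:r000000	ref|f000s00	99.93	246	0	0	0	0	0	0	1.24e-07	491.7	250
S002:r000001	ref|f000s00	91.50	220	0	0	0	0	0	0	7.34e-25	402.6	250
S002:r000002	ref|f000s01	96.61	217	0	0	0	0	0	0	2.81e-28	419.3	250
S002:r000003	ref|f000s01	91.37	237	0	0	0	0	0	0	1.46e-10	433.1	250
S002:r000004	ref|f000s03	90.82	221	0	0	0	0	0	0	6.64e-25	401.4	250
S002:r000005	ref|f000s03	89.81	219	0	0	0	0	0	0	9.61e-25	393.4	250
S002:r000006	ref|f000s03	98.44	220	0	0	0	0	0	0	1.23e-24	433.1	250
S002:r000007	ref|f000s03	88.54	224	0	0	0	0	0	0	6.79e-19	396.7	250
S002:r000008	ref|f000s03	100.00	228	0	0	0	0	0	0	3.76e-20	456.0	250
S002:r000009	ref|f000s03	96.61	227	0	0	0	0	0	0	5.21e-24	438.6	250
S002:r000010	ref|f000s03	92.41	221	0	0	0	0	0	0	2.28e-06	408.5	250
S002:r000011	ref|f000s03	95.15	237	0	0	0	0	0	0	1.85e-26	451.0	250
S002:r000012	ref|f000s03	93.34	226	0	0	0	0	0	0	4.13e-23	421.9	250
S002:r000013	ref|f003s00	91.94	239	0	0	0	0	0	0	0.00374	439.5	250
S002:r000014	ref|f003s00	95.80	206	0	0	0	0	0	0	6.06e-23	394.7	250
S002:r000015	ref|f003s02	99.69	184	0	0	0	0	0	0	6.85e-22	366.9	250
S002:r000016	ref|f005s02	91.19	184	0	0	0	0	0	0	1.61e-15	335.6	250
S002:r000017	ref|f008s01	99.67	242	0	0	0	0	0	0	1.82e-20	482.4	250
S002:r000018	ref|f008s01	91.95	210	0	0	0	0	0	0	4.64e-05	386.2	250
S002:r000019	ref|f008s01	91.33	227	0	0	0	0	0	0	3.63e-24	414.6	250
S002:r000020	ref|f008s01	90.50	235	0	0	0	0	0	0	5.59e-14	425.4	250
S002:r000021	ref|f008s03	91.74	241	0	0	0	0	0	0	2.78e-24	442.2	250
S002:r000022	ref|f008s03	96.97	236	0	0	0	0	0	0	1.98e-14	457.7	250
S002:r000023	ref|f008s03	91.11	213	0	0	0	0	0	0	3.76e-05	388.1	250
S002:r000024	ref|f008s03	95.13	244	0	0	0	0	0	0	5.52e-07	464.2	250
S002:r000025	ref|f008s03	94.21	227	0	0	0	0	0	0	1.87e-12	427.7	250
S002:r000026	ref|f008s03	99.73	205	0	0	0	0	0	0	4.54e-10	408.9	250
S002:r000027	ref|f008s03	100.00	203	0	0	0	0	0	0	1.1e-22	406.0	250
S002:r000028	ref|f008s03	98.73	235	0	0	0	0	0	0	2.92e-16	464.0	250
S002:r000029	ref|f008s03	94.50	240	0	0	0	0	0	0	3.04e-10	453.6	250
S002:r000030	ref|f008s03	85.38	225	0	0	0	0	0	0	5.49e-12	384.2	250
S002:r000031	ref|f008s03	81.09	246	0	0	0	0	0	0	2.95e-16	399.0	250
S002:r000032	ref|f008s03	96.96	231	0	0	0	0	0	0	2.05e-22	447.9	250
S002:r000033	ref|f008s03	90.85	232	0	0	0	0	0	0	1.88e-11	421.6	250
S002:r000034	ref|f008s03	100.00	229	0	0	0	0	0	0	1.31e-05	458.0	250
S002:r000035	ref|f008s03	97.04	188	0	0	0	0	0	0	1.22e-11	364.9	250
S002:r000036	ref|f010s01	95.72	185	0	0	0	0	0	0	1.14e-09	354.2	250
S002:r000037	ref|f010s01	95.39	221	0	0	0	0	0	0	6.43e-08	421.6	250
S002:r000038	ref|f010s01	92.54	235	0	0	0	0	0	0	2.89e-10	434.9	250
S002:r000039	ref|f010s01	94.52	219	0	0	0	0	0	0	5.55e-27	414.0	250
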