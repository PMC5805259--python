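S001:r000000	bact|f000	97.40	223	0	0	0	0	0	0	1e-20	434.4	250
S001:r000001	bact|f000	93.60	216	0	0	0	0	0	0	1e-20	404.3	250
S001:r000002	bact|f000	97.40	239	0	0	0	0	0	0	1e-20	465.6	250
S001:r000003	bact|f000	88.22	220	0	0	0	0	0	0	1e-20	388.2	250
S001:r000004	bact|f000	95.38	212	0	0	0	0	0	0	1e-20	404.4	250
S001:r000005	bact|f000	91.23	237	0	0	0	0	0	0	1e-20	432.4	250
S001:r000006	bact|f000	96.68	249	0	0	0	0	0	0	1e-20	481.5	250
S001:r000007	bact|f000	98.57	216	0	0	0	0	0	0	1e-20	425.8	250
S001:r000008	bact|f003	96.18	225	0	0	0	0	0	0	1e-20	432.8	250
S001:r000010	bact|f005	86.85	239	0	0	0	0	0	0	1e-20	415.1	250
S001:r000011	bact|f005	87.25	223	0	0	0	0	0	0	1e-20	389.1	250
S001:r000012	bact|f005	94.80	245	0	0	0	0	0	0	1e-20	464.5	250
S001:r000013	bact|f005	89.95	233	0	0	0	0	0	0	1e-20	419.2	250
S001:r000014	bact|f005	87.05	230	0	0	0	0	0	0	1e-20	400.4	250
S001:r000015	bact|f005	90.53	232	0	0	0	0	0	0	1e-20	420.1	250
S001:r000016	bact|f006	96.88	234	0	0	0	0	0	0	1e-20	453.4	250
S001:r000017	bact|f006	94.70	220	0	0	0	0	0	0	1e-20	416.7	250
S001:r000018	bact|f006	98.24	239	0	0	0	0	0	0	1e-20	469.6	250
S001:r000019	bact|f006	91.40	223	0	0	0	0	0	0	1e-20	407.7	250
S001:r000020	bact|f006	86.83	202	0	0	0	0	0	0	1e-20	350.8	250
S001:r000021	bact|f007	87.45	243	0	0	0	0	0	0	1e-20	425.0	250
S001:r000022	bact|f007	89.97	195	0	0	0	0	0	0	1e-20	350.9	250
S001:r000023	bact|f008	96.27	213	0	0	0	0	0	0	1e-20	410.1	250
S001:r000024	bact|f008	94.69	231	0	0	0	0	0	0	1e-20	437.5	250
S001:r000025	bact|f009	91.85	170	0	0	0	0	0	0	1e-20	312.3	250
S001:r000026	bact|f009	90.16	222	0	0	0	0	0	0	1e-20	400.3	250
S001:r000027	bact|f009	87.26	219	0	0	0	0	0	0	1e-20	382.2	250
S001:r000028	bact|f009	85.95	234	0	0	0	0	0	0	1e-20	402.3	250
S001:r000030	bact|f009	92.38	239	0	0	0	0	0	0	1e-20	441.6	250
S001:r000031	bact|f009	87.75	232	0	0	0	0	0	0	1e-20	407.2	250
S001:r000032	bact|f009	98.54	228	0	0	0	0	0	0	1e-20	449.3	250
S001:r000033	bact|f009	94.52	201	0	0	0	0	0	0	1e-20	380.0	250
S001:r000034	bact|f009	97.11	235	0	0	0	0	0	0	1e-20	456.4	250
S001:r000035	bact|f009	96.71	230	0	0	0	0	0	0	1e-20	444.9	250
S001:r000036	bact|f009	90.90	231	0	0	0	0	0	0	1e-20	420.0	250
S001:r000037	bact|f009	86.90	222	0	0	0	0	0	0	1e-20	385.8	250
S001:r000038	bact|f009	86.86	197	0	0	0	0	0	0	1e-20	342.2	250
S001:r000039	bact|f010	85.11	178	0	0	0	0	0	0	1e-20	303.0	250
S001:b00000	bact|background	93.59	212	0	0	0	0	0	0	1e-20	396.8	250
S001:b00001	bact|background	98.14	232	0	0	0	0	0	0	1e-20	455.4	250
S001:b00002	bact|background	93.55	214	0	0	0	0	0	0	1e-20	400.4	250
S001:b00003	bact|background	98.18	232	0	0	0	0	0	0	1e-20	455.6	250
S001:b00004	bact|background	91.13	214	0	0	0	0	0	0	1e-20	390.0	250
S001:b00005	bact|background	97.12	243	0	0	0	0	0	0	1e-20	472.0	250
S001:b00006	bact|background	91.97	239	0	0	0	0	0	0	1e-20	439.6	250
S001:b00007	bact|background	91.29	238	0	0	0	0	0	0	1e-20	434.5	250
S001:b00008	bact|background	92.58	237	0	0	0	0	0	0	1e-20	438.8	250
S001:b00009	bact|background	85.69	188	0	0	0	0	0	0	1e-20	322.2	250
S001:b00010	bact|background	89.20	242	0	0	0	0	0	0	1e-20	431.7	250
S001:b00011	bact|background	88.22	228	0	0	0	0	0	0	1e-20	402.3	250
S001:b00012	bact|background	86.98	213	0	0	0	0	0	0	1e-20	370.5	250
S001:b00013	bact|background	94.78	240	0	0	0	0	0	0	1e-20	455.0	250
S001:b00014	bact|background	93.69	207	0	0	0	0	0	0	1e-20	387.9	250
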