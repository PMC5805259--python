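S007:r000000	bact|f000	95.96	224	0	0	0	0	0	0	1e-20	429.9	250
S007:r000001	bact|f000	93.78	225	0	0	0	0	0	0	1e-20	422.0	250
S007:r000002	bact|f000	92.25	232	0	0	0	0	0	0	1e-20	428.1	250
S007:r000003	bact|f000	93.09	230	0	0	0	0	0	0	1e-20	428.2	250
S007:r000004	bact|f000	91.10	203	0	0	0	0	0	0	1e-20	369.8	250
S007:r000005	bact|f000	93.98	214	0	0	0	0	0	0	1e-20	402.3	250
S007:r000006	bact|f000	88.45	234	0	0	0	0	0	0	1e-20	414.0	250
S007:r000007	bact|f000	96.67	236	0	0	0	0	0	0	1e-20	456.3	250
S007:r000008	bact|f000	90.54	239	0	0	0	0	0	0	1e-20	432.8	250
S007:r000009	bact|f000	86.70	241	0	0	0	0	0	0	1e-20	417.9	250
S007:r000012	bact|f005	93.04	216	0	0	0	0	0	0	1e-20	402.0	250
S007:r000013	bact|f005	96.11	160	0	0	0	0	0	0	1e-20	307.6	250
S007:r000014	bact|f005	95.80	247	0	0	0	0	0	0	1e-20	473.2	250
S007:r000015	bact|f005	96.33	218	0	0	0	0	0	0	1e-20	420.0	250
S007:r000017	bact|f006	92.90	221	0	0	0	0	0	0	1e-20	410.6	250
S007:r000018	bact|f007	95.50	231	0	0	0	0	0	0	1e-20	441.2	250
S007:r000020	bact|f008	96.13	249	0	0	0	0	0	0	1e-20	478.7	250
S007:r000021	bact|f008	85.92	220	0	0	0	0	0	0	1e-20	378.0	250
S007:r000022	bact|f008	86.01	195	0	0	0	0	0	0	1e-20	335.4	250
S007:r000023	bact|f008	96.64	227	0	0	0	0	0	0	1e-20	438.8	250
S007:r000024	bact|f008	97.35	238	0	0	0	0	0	0	1e-20	463.4	250
S007:r000025	bact|f008	97.56	226	0	0	0	0	0	0	1e-20	441.0	250
S007:r000026	bact|f008	92.87	217	0	0	0	0	0	0	1e-20	403.0	250
S007:r000027	bact|f008	89.27	233	0	0	0	0	0	0	1e-20	416.0	250
S007:r000028	bact|f008	86.56	233	0	0	0	0	0	0	1e-20	403.4	250
S007:r000029	bact|f008	97.93	247	0	0	0	0	0	0	1e-20	483.8	250
S007:r000030	bact|f008	97.70	237	0	0	0	0	0	0	1e-20	463.1	250
S007:r000031	bact|f008	90.80	177	0	0	0	0	0	0	1e-20	321.4	250
S007:r000032	bact|f010	87.24	241	0	0	0	0	0	0	1e-20	420.5	250
S007:r000033	bact|f010	97.45	225	0	0	0	0	0	0	1e-20	438.5	250
S007:r000034	bact|f010	91.79	228	0	0	0	0	0	0	1e-20	418.6	250
S007:r000036	bact|f010	89.67	204	0	0	0	0	0	0	1e-20	365.9	250
S007:r000037	bact|f010	95.83	198	0	0	0	0	0	0	1e-20	379.5	250
S007:r000038	bact|f010	93.70	224	0	0	0	0	0	0	1e-20	419.8	250
S007:r000039	bact|f010	98.55	243	0	0	0	0	0	0	1e-20	478.9	250
S007:b00000	bact|background	93.58	225	0	0	0	0	0	0	1e-20	421.1	250
S007:b00001	bact|background	85.10	246	0	0	0	0	0	0	1e-20	418.7	250
S007:b00002	bact|background	91.34	238	0	0	0	0	0	0	1e-20	434.8	250
S007:b00003	bact|background	93.87	190	0	0	0	0	0	0	1e-20	356.7	250
S007:b00004	bact|background	90.82	222	0	0	0	0	0	0	1e-20	403.2	250
S007:b00005	bact|background	97.58	180	0	0	0	0	0	0	1e-20	351.3	250
S007:b00006	bact|background	95.17	207	0	0	0	0	0	0	1e-20	394.0	250
S007:b00007	bact|background	96.61	223	0	0	0	0	0	0	1e-20	430.9	250
S007:b00008	bact|background	94.70	221	0	0	0	0	0	0	1e-20	418.6	250
S007:b00009	bact|background	92.63	242	0	0	0	0	0	0	1e-20	448.3	250
S007:b00010	bact|background	86.45	245	0	0	0	0	0	0	1e-20	423.6	250
S007:b00011	bact|background	89.10	223	0	0	0	0	0	0	1e-20	397.4	250
S007:b00012	bact|background	92.09	242	0	0	0	0	0	0	1e-20	445.7	250
S007:b00013	bact|background	91.86	245	0	0	0	0	0	0	1e-20	450.1	250
S007:b00014	bact|background	96.96	224	0	0	0	0	0	0	1e-20	434.4	250
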