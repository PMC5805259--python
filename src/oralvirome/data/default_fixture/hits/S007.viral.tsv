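S007:r000000	ref|f000s01	92.46	219	0	0	0	0	0	0	4.43e-19	405.0	250
S007:r000001	ref|f000s01	97.49	242	0	0	0	0	0	0	2.46e-30	471.8	250
S007:r000002	ref|f000s01	98.47	240	0	0	0	0	0	0	7.27e-21	472.7	250
S007:r000003	ref|f000s01	96.59	215	0	0	0	0	0	0	1.61e-11	415.3	250
S007:r000004	ref|f000s01	93.31	225	0	0	0	0	0	0	6.12e-23	419.9	250
S007:r000005	ref|f000s03	94.32	152	0	0	0	0	0	0	1.35e-26	286.7	250
S007:r000006	ref|f000s03	89.07	244	0	0	0	0	0	0	7.18e-17	434.6	250
S007:r000007	ref|f000s03	96.27	205	0	0	0	0	0	0	1.07e-27	394.7	250
S007:r000008	ref|f000s03	92.75	200	0	0	0	0	0	0	3.38e-18	371.0	250
S007:r000009	ref|f000s03	96.77	232	0	0	0	0	0	0	1.89e-11	449.0	250
S007:r000009	ref|f000s01	96.77	232	0	0	0	0	0	0	1.89e-11	448.5	250
S007:r000010	ref|f002s00	93.36	223	0	0	0	0	0	0	3.52e-14	416.4	250
S007:r000011	ref|f003s02	99.14	215	0	0	0	0	0	0	1.15e-11	426.3	250
S007:r000012	ref|f005s02	95.96	226	0	0	0	0	0	0	9.35e-10	433.7	250
S007:r000013	ref|f005s02	87.67	223	0	0	0	0	0	0	2.32e-14	391.0	250
S007:r000014	ref|f005s02	93.92	232	0	0	0	0	0	0	1.87e-24	435.8	250
S007:r000015	ref|f005s02	100.00	245	0	0	0	0	0	0	5.74e-30	490.0	250
S007:r000016	ref|f006s03	96.66	202	0	0	0	0	0	0	6.53e-28	390.5	250
S007:r000017	ref|f006s03	99.30	210	0	0	0	0	0	0	2.11e-06	417.1	250
S007:r000018	ref|f007s01	94.20	200	0	0	0	0	0	0	3.84e-23	376.8	250
S007:r000019	ref|f008s03	94.72	208	0	0	0	0	0	0	3.34e-21	394.0	250
S007:r000020	ref|f008s03	98.16	215	0	0	0	0	0	0	3.08e-24	422.1	250
S007:r000021	ref|f008s03	97.50	215	0	0	0	0	0	0	3.32e-12	419.2	250
S007:r000022	ref|f008s03	98.07	241	0	0	0	0	0	0	2.32e-15	472.7	250
S007:r000023	ref|f008s03	86.56	231	0	0	0	0	0	0	2.19e-16	399.9	250
S007:r000024	ref|f008s03	92.83	243	0	0	0	0	0	0	1.47e-27	451.2	250
S007:r000025	ref|f008s03	97.34	245	0	0	0	0	0	0	1.66e-12	476.9	250
S007:r000026	ref|f008s03	92.96	202	0	0	0	0	0	0	1.53e-24	375.6	250
S007:r000027	ref|f008s03	97.44	214	0	0	0	0	0	0	2.25e-20	417.0	250
S007:r000028	ref|f008s03	87.73	235	0	0	0	0	0	0	2.97e-12	412.3	250
S007:r000029	ref|f008s03	100.00	247	0	0	0	0	0	0	1.83e-21	494.0	250
S007:r000030	ref|f008s03	96.28	228	0	0	0	0	0	0	3.2e-06	439.0	250
S007:r000030	ref|f008s01	96.28	228	0	0	0	0	0	0	3.2e-06	438.5	250
S007:r000031	ref|f008s03	100.00	234	0	0	0	0	0	0	5.26e-10	468.0	250
S007:r000032	ref|f010s02	95.27	213	0	0	0	0	0	0	7.39e-18	405.8	250
S007:r000033	ref|f010s02	89.33	212	0	0	0	0	0	0	2.12e-27	378.8	250
S007:r000034	ref|f010s02	96.86	241	0	0	0	0	0	0	5.38e-05	466.9	250
S007:r000035	ref|f010s02	84.56	213	0	0	0	0	0	0	2.38e-06	360.2	250
S007:r000036	ref|f010s02	95.15	221	0	0	0	0	0	0	5.09e-13	420.6	250
S007:r000037	ref|f010s02	96.26	230	0	0	0	0	0	0	3.13e-25	442.8	250
S007:r000038	ref|f010s02	95.54	227	0	0	0	0	0	0	3.22e-11	433.8	250
S007:r000038	ref|f010s00	95.54	227	0	0	0	0	0	0	3.22e-11	433.3	250
S007:r000039	ref|f010s02	94.54	245	0	0	0	0	0	0	1.15e-21	463.3	250
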