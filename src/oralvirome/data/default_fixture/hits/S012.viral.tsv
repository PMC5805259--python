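S012:r000000	ref|f000s03	94.77	234	0	0	0	0	0	0	1.64e-06	443.5	250
S012:r000001	ref|f000s03	93.25	234	0	0	0	0	0	0	9.72e-13	436.4	250
S012:r000002	ref|f002s03	89.44	226	0	0	0	0	0	0	1.75e-30	404.3	250
S012:r000003	ref|f002s03	88.94	201	0	0	0	0	0	0	1.62e-24	357.5	250
S012:r000004	ref|f003s02	95.46	227	0	0	0	0	0	0	3.99e-18	433.4	250
S012:r000005	ref|f003s02	93.81	224	0	0	0	0	0	0	7.17e-18	420.3	250
S012:r000006	ref|f004s02	97.21	206	0	0	0	0	0	0	9.48e-09	400.5	250
S012:r000007	ref|f004s02	91.21	242	0	0	0	0	0	0	1.41e-13	441.4	250
S012:r000008	ref|f005s00	91.86	230	0	0	0	0	0	0	2.78e-07	422.5	250
S012:r000009	ref|f005s02	96.07	232	0	0	0	0	0	0	1.15e-07	445.8	250
S012:r000010	ref|f005s02	97.16	234	0	0	0	0	0	0	3.36e-07	454.7	250
S012:r000011	ref|f005s02	94.90	237	0	0	0	0	0	0	2.7e-10	449.8	250
S012:r000012	ref|f005s03	94.17	237	0	0	0	0	0	0	5.01e-28	446.4	250
S012:r000013	ref|f005s03	94.03	232	0	0	0	0	0	0	1.04e-11	436.3	250
S012:r000014	ref|f005s03	97.93	209	0	0	0	0	0	0	3.46e-25	409.4	250
S012:r000015	ref|f005s03	88.69	223	0	0	0	0	0	0	1.85e-18	395.5	250
S012:r000016	ref|f005s03	95.09	245	0	0	0	0	0	0	6.23e-22	465.9	250
S012:r000016	ref|f005s01	95.09	245	0	0	0	0	0	0	6.23e-22	465.4	250
S012:r000017	ref|f006s00	96.31	233	0	0	0	0	0	0	4.14e-14	448.8	250
S012:r000018	ref|f006s00	96.86	248	0	0	0	0	0	0	2.28e-12	480.4	250
S012:r000019	ref|f006s00	98.44	217	0	0	0	0	0	0	2.25e-11	427.2	250
S012:r000020	ref|f006s00	94.76	223	0	0	0	0	0	0	1.89e-14	422.6	250
S012:r000021	ref|f006s00	95.97	229	0	0	0	0	0	0	3.54e-21	439.5	250
S012:r000022	ref|f006s00	94.44	222	0	0	0	0	0	0	3.54e-17	419.3	250
S012:r000023	ref|f006s03	96.00	230	0	0	0	0	0	0	1.61e-22	441.6	250
S012:r000024	ref|f006s03	92.61	245	0	0	0	0	0	0	1.4e-28	453.8	250
S012:r000025	ref|f006s03	95.21	182	0	0	0	0	0	0	1.26e-20	346.6	250
S012:r000026	ref|f007s00	89.16	233	0	0	0	0	0	0	3.74e-15	415.5	250
S012:r000027	ref|f007s02	99.81	229	0	0	0	0	0	0	6.25e-24	457.1	250
S012:r000028	ref|f007s02	90.09	211	0	0	0	0	0	0	5.26e-13	380.2	250
S012:r000029	ref|f008s00	97.20	205	0	0	0	0	0	0	2.23e-20	398.5	250
S012:r000030	ref|f008s00	100.00	235	0	0	0	0	0	0	6.48e-18	470.0	250
S012:r000031	ref|f008s01	88.90	216	0	0	0	0	0	0	6.16e-09	384.1	250
S012:r000032	ref|f008s01	100.00	211	0	0	0	0	0	0	8.58e-12	422.0	250
S012:r000033	ref|f008s03	97.42	211	0	0	0	0	0	0	2.17e-13	411.1	250
S012:r000034	ref|f008s03	99.20	230	0	0	0	0	0	0	7.31e-05	456.3	250
S012:r000035	ref|f010s03	96.54	199	0	0	0	0	0	0	1.23e-17	384.2	250
S012:r000036	ref|f010s03	100.00	225	0	0	0	0	0	0	4.4e-28	450.0	250
S012:r000037	ref|f010s03	96.48	241	0	0	0	0	0	0	4.83e-10	465.0	250
S012:r000038	ref|f010s03	87.43	220	0	0	0	0	0	0	1.34e-18	384.7	250
S012:r000039	ref|f010s03	91.76	238	0	0	0	0	0	0	1.57e-27	436.8	250
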