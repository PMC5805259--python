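taxon	S001	S002	S003	S004	S005	S006	S007	S008	S009	S010	S011	S012
o__Simulavirales_0;f__Simviridae_0;g__Simvirus_0_0;s__Simulated virus 0-0	6	2	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_0;g__Simvirus_0_1;s__Simulated virus 0-1	0	2	0	5	5	2	5	8	12	1	3	0
o__Simulavirales_0;f__Simviridae_0;g__Simvirus_0_0;s__Simulated virus 0-2	0	0	0	1	0	0	0	0	0	2	0	0
o__Simulavirales_0;f__Simviridae_0;g__Simvirus_0_1;s__Simulated virus 0-3	2	9	8	0	10	15	5	4	8	1	1	2
o__Simulavirales_0;f__Simviridae_1;g__Simvirus_1_0;s__Simulated virus 1-0	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_1;g__Simvirus_1_1;s__Simulated virus 1-1	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_1;g__Simvirus_1_0;s__Simulated virus 1-2	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_1;g__Simvirus_1_1;s__Simulated virus 1-3	0	0	0	0	1	0	0	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_2;g__Simvirus_2_0;s__Simulated virus 2-0	0	0	0	0	0	0	1	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_2;g__Simvirus_2_1;s__Simulated virus 2-1	0	0	0	0	0	0	0	1	0	0	0	0
o__Simulavirales_0;f__Simviridae_2;g__Simvirus_2_0;s__Simulated virus 2-2	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_0;f__Simviridae_2;g__Simvirus_2_1;s__Simulated virus 2-3	0	0	0	0	0	0	0	0	0	0	0	2
o__Simulavirales_1;f__Simviridae_3;g__Simvirus_3_0;s__Simulated virus 3-0	0	2	1	4	0	5	0	1	0	3	0	0
o__Simulavirales_1;f__Simviridae_3;g__Simvirus_3_1;s__Simulated virus 3-1	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_1;f__Simviridae_3;g__Simvirus_3_0;s__Simulated virus 3-2	2	1	4	0	3	0	1	1	1	0	2	2
o__Simulavirales_1;f__Simviridae_3;g__Simvirus_3_1;s__Simulated virus 3-3	0	0	1	0	0	0	0	0	0	0	0	0
o__Simulavirales_1;f__Simviridae_4;g__Simvirus_4_0;s__Simulated virus 4-0	0	0	4	0	0	0	0	0	2	0	1	0
o__Simulavirales_1;f__Simviridae_4;g__Simvirus_4_1;s__Simulated virus 4-1	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_1;f__Simviridae_4;g__Simvirus_4_0;s__Simulated virus 4-2	0	0	0	0	0	0	0	0	0	0	0	2
o__Simulavirales_1;f__Simviridae_4;g__Simvirus_4_1;s__Simulated virus 4-3	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_1;f__Simviridae_5;g__Simvirus_5_0;s__Simulated virus 5-0	0	0	0	2	0	5	0	0	0	1	0	1
o__Simulavirales_1;f__Simviridae_5;g__Simvirus_5_1;s__Simulated virus 5-1	0	0	1	0	0	0	0	0	7	0	0	0
o__Simulavirales_1;f__Simviridae_5;g__Simvirus_5_0;s__Simulated virus 5-2	6	1	2	18	11	2	4	0	5	0	0	3
o__Simulavirales_1;f__Simviridae_5;g__Simvirus_5_1;s__Simulated virus 5-3	0	0	0	1	0	0	0	0	0	11	0	5
o__Simulavirales_2;f__Simviridae_6;g__Simvirus_6_0;s__Simulated virus 6-0	0	0	0	0	0	0	0	0	0	0	0	6
o__Simulavirales_2;f__Simviridae_6;g__Simvirus_6_1;s__Simulated virus 6-1	0	0	0	0	0	0	0	0	1	0	0	0
o__Simulavirales_2;f__Simviridae_6;g__Simvirus_6_0;s__Simulated virus 6-2	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_2;f__Simviridae_6;g__Simvirus_6_1;s__Simulated virus 6-3	5	0	13	3	5	5	2	17	3	2	4	3
o__Simulavirales_2;f__Simviridae_7;g__Simvirus_7_0;s__Simulated virus 7-0	0	0	0	0	0	0	0	0	0	0	0	1
o__Simulavirales_2;f__Simviridae_7;g__Simvirus_7_1;s__Simulated virus 7-1	1	0	0	0	0	0	1	0	0	0	0	0
o__Simulavirales_2;f__Simviridae_7;g__Simvirus_7_0;s__Simulated virus 7-2	1	0	0	0	1	0	0	0	0	0	0	2
o__Simulavirales_2;f__Simviridae_7;g__Simvirus_7_1;s__Simulated virus 7-3	0	0	0	2	0	0	0	0	0	0	0	0
o__Simulavirales_2;f__Simviridae_8;g__Simvirus_8_0;s__Simulated virus 8-0	0	0	0	0	0	1	0	1	0	0	0	2
o__Simulavirales_2;f__Simviridae_8;g__Simvirus_8_1;s__Simulated virus 8-1	0	4	0	0	0	0	0	0	0	0	0	2
o__Simulavirales_2;f__Simviridae_8;g__Simvirus_8_0;s__Simulated virus 8-2	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_2;f__Simviridae_8;g__Simvirus_8_1;s__Simulated virus 8-3	2	15	2	2	3	5	13	2	0	4	28	2
o__Simulavirales_3;f__Simviridae_9;g__Simvirus_9_0;s__Simulated virus 9-0	0	0	0	0	0	0	0	0	0	0	1	0
o__Simulavirales_3;f__Simviridae_9;g__Simvirus_9_1;s__Simulated virus 9-1	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_3;f__Simviridae_9;g__Simvirus_9_0;s__Simulated virus 9-2	14	0	0	0	0	0	0	0	0	15	0	0
o__Simulavirales_3;f__Simviridae_9;g__Simvirus_9_1;s__Simulated virus 9-3	0	0	1	0	1	0	0	2	0	0	0	0
o__Simulavirales_3;f__Simviridae_10;g__Simvirus_10_0;s__Simulated virus 10-0	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_3;f__Simviridae_10;g__Simvirus_10_1;s__Simulated virus 10-1	0	4	2	0	0	0	0	0	0	0	0	0
o__Simulavirales_3;f__Simviridae_10;g__Simvirus_10_0;s__Simulated virus 10-2	1	0	0	1	0	0	8	2	0	0	0	0
o__Simulavirales_3;f__Simviridae_10;g__Simvirus_10_1;s__Simulated virus 10-3	0	0	1	0	0	0	0	0	0	0	0	5
o__Simulavirales_3;f__Simviridae_11;g__Simvirus_11_0;s__Simulated virus 11-0	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_3;f__Simviridae_11;g__Simvirus_11_1;s__Simulated virus 11-1	0	0	0	1	0	0	0	0	0	0	0	0
o__Simulavirales_3;f__Simviridae_11;g__Simvirus_11_0;s__Simulated virus 11-2	0	0	0	0	0	0	0	0	0	0	0	0
o__Simulavirales_3;f__Simviridae_11;g__Simvirus_11_1;s__Simulated virus 11-3	0	0	0	0	0	0	0	1	1	0	0	0
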