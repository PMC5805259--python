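taxon_id	name	rank	parent_id
o00	Simulavirales_0	order	
o01	Simulavirales_1	order	
o02	Simulavirales_2	order	
o03	Simulavirales_3	order	
f000	Simviridae_0	family	o00
f000g0	Simvirus_0_0	genus	f000
f000g1	Simvirus_0_1	genus	f000
f000s00	Simulated virus 0-0	species	f000g0
f000s01	Simulated virus 0-1	species	f000g1
f000s02	Simulated virus 0-2	species	f000g0
f000s03	Simulated virus 0-3	species	f000g1
f001	Simviridae_1	family	o00
f001g0	Simvirus_1_0	genus	f001
f001g1	Simvirus_1_1	genus	f001
f001s00	Simulated virus 1-0	species	f001g0
f001s01	Simulated virus 1-1	species	f001g1
f001s02	Simulated virus 1-2	species	f001g0
f001s03	Simulated virus 1-3	species	f001g1
f002	Simviridae_2	family	o00
f002g0	Simvirus_2_0	genus	f002
f002g1	Simvirus_2_1	genus	f002
f002s00	Simulated virus 2-0	species	f002g0
f002s01	Simulated virus 2-1	species	f002g1
f002s02	Simulated virus 2-2	species	f002g0
f002s03	Simulated virus 2-3	species	f002g1
f003	Simviridae_3	family	o01
f003g0	Simvirus_3_0	genus	f003
f003g1	Simvirus_3_1	genus	f003
f003s00	Simulated virus 3-0	species	f003g0
f003s01	Simulated virus 3-1	species	f003g1
f003s02	Simulated virus 3-2	species	f003g0
f003s03	Simulated virus 3-3	species	f003g1
f004	Simviridae_4	family	o01
f004g0	Simvirus_4_0	genus	f004
f004g1	Simvirus_4_1	genus	f004
f004s00	Simulated virus 4-0	species	f004g0
f004s01	Simulated virus 4-1	species	f004g1
f004s02	Simulated virus 4-2	species	f004g0
f004s03	Simulated virus 4-3	species	f004g1
f005	Simviridae_5	family	o01
f005g0	Simvirus_5_0	genus	f005
f005g1	Simvirus_5_1	genus	f005
f005s00	Simulated virus 5-0	species	f005g0
f005s01	Simulated virus 5-1	species	f005g1
f005s02	Simulated virus 5-2	species	f005g0
f005s03	Simulated virus 5-3	species	f005g1
f006	Simviridae_6	family	o02
f006g0	Simvirus_6_0	genus	f006
f006g1	Simvirus_6_1	genus	f006
f006s00	Simulated virus 6-0	species	f006g0
f006s01	Simulated virus 6-1	species	f006g1
f006s02	Simulated virus 6-2	species	f006g0
f006s03	Simulated virus 6-3	species	f006g1
f007	Simviridae_7	family	o02
f007g0	Simvirus_7_0	genus	f007
f007g1	Simvirus_7_1	genus	f007
f007s00	Simulated virus 7-0	species	f007g0
f007s01	Simulated virus 7-1	species	f007g1
f007s02	Simulated virus 7-2	species	f007g0
f007s03	Simulated virus 7-3	species	f007g1
f008	Simviridae_8	family	o02
f008g0	Simvirus_8_0	genus	f008
f008g1	Simvirus_8_1	genus	f008
f008s00	Simulated virus 8-0	species	f008g0
f008s01	Simulated virus 8-1	species	f008g1
f008s02	Simulated virus 8-2	species	f008g0
f008s03	Simulated virus 8-3	species	f008g1
f009	Simviridae_9	family	o03
f009g0	Simvirus_9_0	genus	f009
f009g1	Simvirus_9_1	genus	f009
f009s00	Simulated virus 9-0	species	f009g0
f009s01	Simulated virus 9-1	species	f009g1
f009s02	Simulated virus 9-2	species	f009g0
f009s03	Simulated virus 9-3	species	f009g1
f010	Simviridae_10	family	o03
f010g0	Simvirus_10_0	genus	f010
f010g1	Simvirus_10_1	genus	f010
f010s00	Simulated virus 10-0	species	f010g0
f010s01	Simulated virus 10-1	species	f010g1
f010s02	Simulated virus 10-2	species	f010g0
f010s03	Simulated virus 10-3	species	f010g1
f011	Simviridae_11	family	o03
f011g0	Simvirus_11_0	genus	f011
f011g1	Simvirus_11_1	genus	f011
f011s00	Simulated virus 11-0	species	f011g0
f011s01	Simulated virus 11-1	species	f011g1
f011s02	Simulated virus 11-2	species	f011g0
f011s03	Simulated virus 11-3	species	f011g1
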