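subject_id	taxon_id	viral_class
ref|f000s00	f000s00	prophage
ref|f000s01	f000s01	prophage
ref|f000s02	f000s02	prophage
ref|f000s03	f000s03	prophage
ref|f001s00	f001s00	bacteriophage
ref|f001s01	f001s01	bacteriophage
ref|f001s02	f001s02	bacteriophage
ref|f001s03	f001s03	bacteriophage
ref|f002s00	f002s00	bacteriophage
ref|f002s01	f002s01	bacteriophage
ref|f002s02	f002s02	bacteriophage
ref|f002s03	f002s03	bacteriophage
ref|f003s00	f003s00	bacteriophage
ref|f003s01	f003s01	bacteriophage
ref|f003s02	f003s02	bacteriophage
ref|f003s03	f003s03	bacteriophage
ref|f004s00	f004s00	prophage
ref|f004s01	f004s01	prophage
ref|f004s02	f004s02	prophage
ref|f004s03	f004s03	prophage
ref|f005s00	f005s00	prophage
ref|f005s01	f005s01	prophage
ref|f005s02	f005s02	prophage
ref|f005s03	f005s03	prophage
ref|f006s00	f006s00	prophage
ref|f006s01	f006s01	prophage
ref|f006s02	f006s02	prophage
ref|f006s03	f006s03	prophage
ref|f007s00	f007s00	prophage
ref|f007s01	f007s01	prophage
ref|f007s02	f007s02	prophage
ref|f007s03	f007s03	prophage
ref|f008s00	f008s00	prophage
ref|f008s01	f008s01	prophage
ref|f008s02	f008s02	prophage
ref|f008s03	f008s03	prophage
ref|f009s00	f009s00	prophage
ref|f009s01	f009s01	prophage
ref|f009s02	f009s02	prophage
ref|f009s03	f009s03	prophage
ref|f010s00	f010s00	prophage
ref|f010s01	f010s01	prophage
ref|f010s02	f010s02	prophage
ref|f010s03	f010s03	prophage
ref|f011s00	f011s00	bacteriophage
ref|f011s01	f011s01	bacteriophage
ref|f011s02	f011s02	bacteriophage
ref|f011s03	f011s03	bacteriophage
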