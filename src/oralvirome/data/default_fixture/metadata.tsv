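#sample_id	sex
S001	F
S002	F
S003	F
S004	F
S005	F
S006	F
S007	M
S008	M
S009	M
S010	M
S011	M
S012	M
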