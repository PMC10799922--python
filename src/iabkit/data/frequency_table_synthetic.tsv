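# Synthetic toy positional amino-acid frequency table (abYsis-style) for tests/demos.
# source=iabkit_toy version=1 n_sequences=100000
kabat_label	residue	frequency
3	D	0.015500
3	E	0.015500
3	F	0.008000
3	G	0.015500
3	L	0.030000
3	N	0.015500
3	Q	0.900000
5	D	0.015500
5	E	0.015500
5	F	0.030000
5	G	0.015500
5	I	0.008000
5	L	0.620000
5	N	0.015500
5	Q	0.100000
5	V	0.180000
6	D	0.023750
6	E	0.720000
6	G	0.023750
6	H	0.023750
6	N	0.023750
6	Q	0.180000
6	R	0.005000
16	D	0.005000
16	E	0.100000
16	G	0.620000
16	H	0.023750
16	K	0.023750
16	N	0.023750
16	Q	0.023750
16	S	0.180000
19	D	0.014250
19	E	0.014250
19	G	0.014250
19	K	0.180000
19	L	0.008000
19	N	0.014250
19	R	0.625000
19	S	0.100000
19	V	0.030000
23	A	0.800000
23	D	0.015500
23	E	0.015500
23	G	0.015500
23	I	0.030000
23	N	0.015500
23	V	0.108000
57	D	0.023750
57	E	0.005000
57	G	0.023750
57	N	0.023750
57	Q	0.023750
57	T	0.900000
68	D	0.015500
68	E	0.015500
68	G	0.015500
68	I	0.030000
68	N	0.015500
68	T	0.900000
68	V	0.008000
70	D	0.015500
70	E	0.015500
70	G	0.015500
70	L	0.030000
70	M	0.008000
70	N	0.015500
70	S	0.720000
70	T	0.180000
72	D	0.900000
72	E	0.015500
72	F	0.030000
72	G	0.015500
72	L	0.008000
72	N	0.015500
72	Q	0.015500
75	D	0.023750
75	E	0.023750
75	G	0.023750
75	K	0.725000
75	N	0.023750
75	T	0.180000
76	D	0.015500
76	E	0.015500
76	G	0.015500
76	I	0.008000
76	L	0.030000
76	N	0.720000
76	Q	0.015500
76	S	0.180000
77	D	0.023750
77	E	0.023750
77	G	0.023750
77	N	0.023750
77	Q	0.100000
77	T	0.805000
79	D	0.015500
79	E	0.015500
79	G	0.015500
79	I	0.030000
79	N	0.015500
79	S	0.100000
79	V	0.008000
79	Y	0.800000
81	D	0.015500
81	E	0.180000
81	G	0.015500
81	H	0.015500
81	I	0.008000
81	K	0.100000
81	L	0.030000
81	N	0.015500
81	Q	0.620000
84	A	0.720000
84	D	0.023750
84	E	0.023750
84	G	0.023750
84	N	0.005000
84	Q	0.023750
84	S	0.180000
112	D	0.023750
112	E	0.023750
112	G	0.023750
112	N	0.023750
112	S	0.900000
112	V	0.005000
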