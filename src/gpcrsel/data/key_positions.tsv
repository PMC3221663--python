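# Ballesteros-Weinstein labels for 7TM MSA codon columns (1-based), with the
# ten binding-cavity key positions flagged. Columns without a known BW label
# in the packaged map are simply absent from this file.
column_index	bw_index	is_key
8	1.37	0
19	1.48	0
49	2.56	0
50	2.57	0
53	2.60	0
57	2.64	0
61	3.22	0
62	3.23	0
64	3.25	0
65	3.26	0
68	3.29	1
69	3.30	0
71	3.32	1
72	3.33	1
77	3.38	0
110	4.56	0
114	4.60	1
117	5.35	1
121	5.39	1
124	5.42	1
168	6.55	1
171	7.35	1
175	7.39	1
179	7.43	0
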