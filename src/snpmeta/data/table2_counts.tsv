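covariate	level	low_count	high_count
age	<=65	110	74
age	>65	95	128
gender	Female	74	71
gender	Male	132	135
histologic_grade	G1	6	6
histologic_grade	G2	67	81
histologic_grade	G3	128	115
stage	I	25	33
stage	II	68	54
stage	III	88	81
stage	IV	15	24
T	T1	11	11
T	T2	38	50
T	T3	101	80
T	T4	55	58
M	M0	186	179
M	M1	11	15
N	N0	62	62
N	N1	51	58
N	N2	41	37
N	N3	44	38
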