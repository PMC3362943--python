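# SSR motif classes mined from the non-redundant white-clover EST set
# (6.0 Mbp) and the number of EST-SSR primer pairs designed per motif by
# mismatch class; used as reference input for motif-report arithmetic.
motif	unit_len	n_ssr	designed_m0	designed_m1	designed_m2
AG	2	211	30	19	44
AT	2	22	7	3	15
AC	2	8	4	6	11
GC	2	0	0	0	0
AAC	3	182	49	64	139
AAG	3	179	35	90	246
GGT	3	170	27	63	157
ATC	3	113	30	49	151
AAT	3	86	17	21	66
AGC	3	79	8	33	90
GGA	3	36	10	34	89
GGC	3	19	2	8	47
ACT	3	16	5	12	21
ACG	3	4	0	5	21
AATG	4	26	3	12	19
AAAT	4	23	4	13	30
AAAG	4	20	3	5	44
AGTG	4	8	0	0	0
ATAG	4	8	0	0	0
AATT	4	8	3	2	17
ATAC	4	5	0	0	0
AACC	4	4	0	0	0
AAAC	4	4	0	9	34
AACT	4	3	0	0	0
OTHER_TETRA	4	32	4	8	35
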