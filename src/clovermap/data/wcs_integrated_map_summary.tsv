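# Per-linkage-group locus counts and lengths of the integrated white-clover
# map (LG6a carries the fallback values computed from its two parental maps
# because it could not be integrated).
lg	n_loci	length_cm
1a	106	159.1
1b	113	190.9
2a	107	122.9
2b	98	207.8
3a	124	172.5
3b	146	142.6
4a	141	157.0
4b	134	177.1
5a	118	164.5
5b	108	156.2
6a	44	109.08
6b	63	132.4
7a	86	155.7
7b	101	151.5
8a	146	166.1
8b	108	146.0
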