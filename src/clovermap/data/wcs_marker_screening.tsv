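# SSR marker screening outcomes on the '273-7' x 'T17-349' full-sib family:
# markers screened, polymorphic markers, and mapped markers/loci per source
# panel (white-clover EST-SSR 'WCS', red-clover 'RCS', and previously
# published panels).
source	n_screened	n_polymorphic	n_mapped_markers	n_mapped_loci
WCS	1973	874	814	1200
RCS	2518	305	282	412
prs	32	18	17	20
ats	30	27	27	41
TRSSR	26	22	20	26
MTIC	2	2	2	3
MT_EST	36	28	25	38
MT1	2	2	2	3
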