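chrom	total_snps	snps_in_blocks	tag_snps	n_blocks	mean_span_cm	total_haplotypes	mean_haplotypes
1A	419	392	187	65	1.01	290	4.46
1B	295	275	177	69	0.69	284	4.12
2A	304	281	134	52	1.29	220	4.23
2B	529	491	261	96	1.12	410	4.27
3A	340	320	162	53	1.35	232	4.38
3B	373	328	209	79	0.69	332	4.20
4A	315	287	117	43	1.84	168	3.91
4B	140	125	81	29	1.52	126	4.34
5A	357	330	171	65	1.10	277	4.26
5B	472	441	215	77	1.20	335	4.35
6A	342	331	132	47	1.86	212	4.51
6B	351	314	185	70	0.77	279	3.99
7A	343	319	182	81	0.72	290	3.58
7B	236	214	134	52	1.06	216	4.15
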