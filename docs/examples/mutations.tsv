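# dialect example; one row per call per sample
sample_id	chrom	pos	ref	alt	alt_reads	total_reads	gene
a	1	1000	C	G	58	134	
a	1	2000	G	T	61	171	
a	1	3000	T	A	62	149	
a	1	4000	A	C	43	142	
b	1	1000	C	G	49	146	
b	1	2000	G	T	50	158	
b	1	3000	T	A	40	131	
b	1	4000	A	C	47	139	
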