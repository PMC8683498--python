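sample_id	chrom	start	end	total_cn
a	1	1	10000000	2
b	1	1	10000000	2
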