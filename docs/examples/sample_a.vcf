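##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##contig=<ID=1,length=5000>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	a
1	1000	.	C	G	.	.	.	AD:DP	76,58:134
1	2000	.	G	T	.	.	.	AD:DP	110,61:171
1	3000	.	T	A	.	.	.	AD:DP	87,62:149
1	4000	.	A	C	.	.	.	AD:DP	99,43:142
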