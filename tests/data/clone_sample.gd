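#=GENOME_DIFF	1.0
#=TITLE	sim_clone_1
#=POPULATION	p2
#=DAY	127
#=CYCLE	0
#=MUTATOR	false
SNP	1	.	NC_000913	4181245	T	gene_name=rpoB	aa_position=1272	snp_type=nonsynonymous	ref_seq=C
SNP	2	.	NC_000913	2314000	A	gene_name=acnB	aa_position=88	snp_type=synonymous	ref_seq=G
SNP	3	.	NC_000913	1500000	C	snp_type=intergenic	ref_seq=T
DEL	4	.	NC_000913	3000000	12000
INS	5	.	NC_000913	2100000	G	gene_name=yfjK
JC	6	.	NC_000913	1000000	1	NC_000913	1200000	-1	0
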