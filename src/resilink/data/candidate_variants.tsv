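snp	chrom	pos	gene	variant_type	maf_controls	maf_cases	kg1000	exac
rs142787485	2	26358156	RAB10	3UTR	0.041	0.028	0.0152	NA
rs77747916	2	29405333	CLIP4	3UTR	0.0099	0.0069	0.0087	NA
rs41291171	2	33623713	LTBP1	3UTR	0.049	0.049	0.0243	NA
rs7653	10	71910316	SAR1A	3UTR	0.03	0.0092	0.0175	NA
rs143318821	10	102105884	SCD	Promoter	NA	NA	0.004	NA
rs41562219	10	103340081	POLL	Exonic	0.0075	0.0080	0.0029	0.0034
chr10:103347900	10	103347900	POLL;DPCD	Promoter;5UTR	0.0012	0	NA	NA
rs116928523	10	103912209	NOLC1	Exonic	0.0075	0.0057	0.003	0.006
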