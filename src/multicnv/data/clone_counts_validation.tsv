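sample_id	variant_id	n_uncut	n_cut	exome_genotype	exome_cn	uncut_allele	orthogonal_cn
NA07056	rs140952426	60	41	AAGG	4	A
NA12044	rs140952426	4	74	GGGG	4	A
NA18956	rs140952426	44	123	AGGG	4	A
NA12004	rs140952426	37	139	AGGG	4	A
NA12156	rs140952426	13	146	AGGGG	5	A
NA07056	rs200757797	3	84	CCCC	4	T
NA12044	rs200757797	18	53	CCCT	4	T
NA07357	rs200757797	5	79	CCCCCT	6	T
NA12763	rs200757797	22	178	CCCT	4	T	6
NA12874	rs200757797	16	53	CCCT	4	T
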