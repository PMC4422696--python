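target_accession	direction	valence	link_scope	evidence_source	free_text
P08913	lof	beneficial	direct_diabetes	OMIM	LOF, rescue insulin secretion in congenic islets
P14555	gof	harmful	direct_diabetes	ref15	GOF, deleterious to normal beta-cell secretory function
P06276	lof	beneficial	direct_diabetes	ref16	LOF, potentiate insulin action
P35228	gof	harmful	direct_diabetes	OMIM	GOF, impair beta-cell function
P35228	lof	beneficial	direct_diabetes	ref17	LOF, reversed fasting hyperglycemia
P35354	lof	beneficial	direct_diabetes	ref18	LOF, increase insulin secretion
P35354	gof	harmful	direct_diabetes	ref19	GOF, IDDM
Q05586	gof	beneficial	direct_diabetes	ref20	GOF, lower glucose production
P08908	lof	harmful	direct_diabetes	ref21	LOF, impair insulin secretion
P50416	lof	beneficial	direct_diabetes	OMIM;ref22	LOF, decrease glucose production and reduce insulin resistance
Q13639	gof	beneficial	direct_diabetes	ref23	GOF, improve insulin sensitivity
P14784	gof	beneficial	direct_diabetes	ref24	GOF, reverse/prevent diabetes
Q04759	lof	beneficial	direct_diabetes	OMIM	LOF, prevent insulin resistance
P49286	lof	harmful	direct_diabetes	OMIM	LOF, type 2 diabetes
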