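chrom	pos	ref	alt	gene	dbsnp	maf_1000g	freq_98_cases	freq_249_controls	func_class	phylop	sift	polyphen2	lrt	mutation_taster	flags
3	137786409	A	C	DZIP1L	.	.	.	.	nonsynonymous_SNV	C	T	D	N	N	.
3	142542415	C	T	PCOLCE2	rs147612568	0.0014	.	.	nonsynonymous_SNV	C	D	D	D	D	.
3	151171329	G	T	IGSF10	rs143721392	.	.	.	nonsynonymous_SNV	C	D	D	D	N	.
3	151598890	T	C	SUCNR1	.	.	.	.	nonsynonymous_SNV	C	D	D	D	.	prediction_string_ambiguous
9	107331452	G	A	OR13C8	.	.	.	.	nonsynonymous_SNV	C	T	B	N	.	.
9	111947836	GGA	-	EPB41L4B	.	0.002	.	.	nonframeshift_deletion	.	.	.	.	.	.
9	139369066	G	A	SEC16A	rs148167113	0.01	0.0153	0.004	nonsynonymous_SNV	.	.	.	.	.	.
9	139401233	C	T	NOTCH1	rs61751543	0.01	0.0204	0.01	nonsynonymous_SNV	C	T	D	D	D	.
12	10954583	A	T	TAS2R7	rs139604652	0.0032	0.0051	.	nonsynonymous_SNV	C	D	D	N	N	.
22	30733787	C	T	SF3A1	.	.	.	.	nonsynonymous_SNV	C	T	P	D	D	.
22	30951208	C	T	GAL3ST1	rs139452633	0.0005	.	0.004	nonsynonymous_SNV	C	D	D	D	D	.
22	38111897	C	T	TRIOBP	rs143157673	0.0018	.	.	nonsynonymous_SNV	N	.	P	.	.	.
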