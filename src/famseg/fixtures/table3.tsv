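chrom	pos	ref	alt	dbsnp	gene	func_class	maf_1000g	freq_249_controls	freq_98_cases	phylop	sift	polyphen2	lrt	mutation_taster	fam_single_carrier	fam_segregating	fam_nonsegregating	flags
3	137786496	G	A	.	DZIP1L	stopgain_SNV	.	.	0.0051	N	.	.	N	D	0	0	1	counts_ambiguous
3	137790616	C	T	rs150466957	DZIP1L	nonsynonymous_SNV	0.0009	.	0.0051	N	D	P	N	N	1	0	0	.
3	137813726	G	A	rs148594666	DZIP1L	nonsynonymous_SNV	0.0009	.	0.0051	C	T	P	N	N	1	0	0	.
3	142539852	C	T	.	PCOLCE2	nonsynonymous_SNV	.	0.002	0.0051	C	T	B	D	N	1	0	0	freq_ambiguous
3	142548681	C	T	rs140721173	PCOLCE2	nonsynonymous_SNV	0.0009	0.002	0.0051	N	T	B	D	D	1	0	0	.
3	151163838	T	C	rs34114908	IGSF10	nonsynonymous_SNV	0.01	0.01	0.0357	N	D	B	N	N	2	1	3	counts_ambiguous
3	151165241	G	C	rs142202060	IGSF10	nonsynonymous_SNV	0.0005	0.004	0.0102	C	D	P	N	N	1	0	0	counts_ambiguous
3	151165532	G	C	rs35667704	IGSF10	nonsynonymous_SNV	0.0037	0.0141	0.0153	N	D	P	N	N	1	0	1	counts_ambiguous
3	151166124	A	G	rs146828199	IGSF10	nonsynonymous_SNV	.	.	0.0051	C	D	D	N	D	1	0	0	.
9	107332377	T	A	rs76017116	OR13C8	nonsynonymous_SNV	0.01	0.004	0.0153	C	D	B	D	D	3	0	0	.
9	111954616	C	T	rs199718023	EPB41L4B	nonsynonymous_SNV	.	.	0.0051	C	D	B	N	N	1	0	0	.
9	111954622	C	T	rs201059767	EPB41L4B	nonsynonymous_SNV	0.0	.	.	C	D	B	N	N	1	0	0	freq_ambiguous
9	112029768	C	T	.	EPB41L4B	nonsynonymous_SNV	.	.	0.0051	C	T	B	N	.	1	0	0	.
9	112082510	C	T	rs117569740	EPB41L4B	nonsynonymous_SNV	0.14	0.1124	0.1531	C	D	B	.	.	8	4	14	counts_ambiguous
9	139345847	G	A	rs45519739	SEC16A	nonsynonymous_SNV	0.01	.	0.0153	.	.	.	.	.	1	1	0	counts_ambiguous
9	139348749	G	A	rs79974534	SEC16A	nonsynonymous_SNV	0.01	0.0141	0.0306	.	.	.	.	.	1	1	2	counts_ambiguous
9	139360781	G	A	rs199798606	SEC16A	nonsynonymous_SNV	.	0.004	0.0051	.	.	.	.	.	1	0	0	.
9	139368953	G	A	rs3812594	SEC16A	nonsynonymous_SNV	0.16	0.2048	0.2653	.	.	.	.	.	9	9	17	counts_ambiguous
9	139369066	G	A	rs148167113	SEC16A	nonsynonymous_SNV	0.01	0.004	0.0153	.	.	.	.	.	1	0	2	counts_ambiguous
9	139369091	C	T	rs11788702	SEC16A	nonsynonymous_SNV	0.0005	.	0.0051	.	.	.	.	.	1	0	0	.
9	139369408	C	T	rs200238338	SEC16A	nonsynonymous_SNV	.	.	0.0051	.	.	.	.	.	1	0	0	.
9	139369816	G	C	rs200394508	SEC16A	nonsynonymous_SNV	.	.	0.0204	.	.	.	.	.	1	0	3	counts_ambiguous
9	139370955	del9	-	.	SEC16A	nonframeshift_deletion	.	0.008	0.0153	.	.	.	.	.	1	0	2	counts_ambiguous,allele_as_printed
9	139401233	C	T	rs61751543	NOTCH1	nonsynonymous_SNV	0.01	0.01	0.0204	C	T	D	D	D	2	0	2	counts_ambiguous
9	139409775	C	T	rs201077220	NOTCH1	nonsynonymous_SNV	0.0009	.	0.0051	C	T	B	.	D	1	0	0	.
12	10954258	C	T	rs619381	TAS2R7	nonsynonymous_SNV	0.07	0.0884	0.1173	N	T	D	N	N	15	1	2	counts_ambiguous
12	10954583	A	T	rs139604652	TAS2R7	nonsynonymous_SNV	0.0032	.	0.0051	C	D	D	N	N	1	0	0	.
22	30742345	T	G	.	SF3A1	nonsynonymous_SNV	.	.	0.0102	C	T	P	D	D	2	0	0	.
22	30953280	C	T	rs55674628	GAL3ST1	nonsynonymous_SNV	0.01	0.0161	0.0204	C	T	B	N	N	2	0	3	counts_ambiguous
22	38120338	G	A	.	TRIOBP	nonsynonymous_SNV	.	.	0.0051	N	.	D	.	.	1	0	0	.
22	38120542	C	T	rs142024473	TRIOBP	nonsynonymous_SNV	0.03	0.0201	0.0459	C	.	P	.	.	1	1	6	counts_ambiguous
22	38120985	A	G	.	TRIOBP	nonsynonymous_SNV	.	.	0.0051	N	.	D	.	.	1	0	0	.
22	38121040	C	T	rs41296243	TRIOBP	nonsynonymous_SNV	0.01	0.0201	0.0306	N	.	P	.	.	2	1	2	counts_ambiguous
22	38121795	C	T	rs200359708	TRIOBP	nonsynonymous_SNV	0.0018	.	0.0051	C	.	D	.	.	1	0	0	.
22	38122414	AG	-	.	TRIOBP	frameshift_deletion	.	.	0.0051	.	.	.	.	.	0	0	1	counts_ambiguous
22	38129388	G	A	rs34066624	TRIOBP	nonsynonymous_SNV	0.0023	0.008	0.0204	C	.	.	.	.	1	0	3	counts_ambiguous
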