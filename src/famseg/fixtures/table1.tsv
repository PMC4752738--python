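chrom	pos	ref	alt	gene	dbsnp	maf_1000g	func_class	Co-441	Co-634	Co-666	Co-667	Co-771	Co-652	Co-692	Co-657
1	235577776	C	T	TBCE	rs62620041	0.0023	nonsynonymous_SNV	C/T	C/C	C/T	C/T	C/T	C/C	C/C	C/C
2	29295186	C	T	C2orf71	rs75276619	0.01	nonsynonymous_SNV	C/T	C/T	C/T	C/C	C/T	C/C	C/T	C/C
2	155555406	A	G	KCNJ3	rs16838016	0.0032	nonsynonymous_SNV	A/G	A/A	A/G	A/G	A/G	A/G	A/A	A/G
2	169870004	G	A	ABCB11	rs11568361	.	nonsynonymous_SNV	A/G	G/G	A/G	A/G	A/G	A/G	G/G	G/G
3	137786409	A	C	DZIP1L	.	.	nonsynonymous_SNV	A/C	A/C	A/C	A/C	A/C	A/C	A/A	A/C
3	142542415	C	T	PCOLCE2	rs147612568	0.0014	nonsynonymous_SNV	C/T	C/T	C/T	C/T	C/T	C/T	C/C	C/T
3	151171329	G	T	IGSF10	rs143721392	.	nonsynonymous_SNV	G/T	G/T	G/T	G/T	G/T	G/T	G/T	G/T
3	151598890	T	C	SUCNR1	.	.	nonsynonymous_SNV	C/T	C/T	C/T	C/T	C/T	C/T	C/T	C/T
4	13590380	A	G	BOD1L1	rs140964488	0.0009	nonsynonymous_SNV	A/G	A/G	A/G	A/A	A/G	A/A	A/G	A/A
4	22440018	C	G	GPR125	rs144997202	0.0005	nonsynonymous_SNV	C/G	C/G	C/G	C/C	C/G	C/G	C/G	C/C
4	25849449	G	A	SEL1L3	.	.	nonsynonymous_SNV	A/G	A/G	A/G	G/G	A/G	A/G	A/G	G/G
7	141765172	A	T	MGAM	.	.	nonsynonymous_SNV	A/T	A/T	A/T	A/A	A/T	A/A	A/A	A/A
9	107331452	G	A	OR13C8	.	.	nonsynonymous_SNV	A/G	A/G	A/G	A/G	A/G	G/G	G/G	G/G
9	111947836	GGA	-	EPB41L4B	.	.	nonframeshift_deletion	GGA/-	GGA/-	GGA/-	GGA/-	GGA/-	GGA/GGA	GGA/GGA	GGA/GGA
9	139369066	G	A	SEC16A	rs148167113	0.01	nonsynonymous_SNV	A/G	A/G	A/G	A/G	A/G	A/G	A/G	A/G
9	139401233	C	T	NOTCH1	rs61751543	0.01	nonsynonymous_SNV	C/T	C/T	C/T	C/T	C/T	C/T	C/T	C/T
10	5931230	C	T	ANKRD16	rs3750659	0.06	nonsynonymous_SNV	C/T	C/T	C/T	C/C	C/T	C/C	C/C	C/C
11	130784886	T	C	SNX19	rs117260465	0.01	nonsynonymous_SNV	C/T	C/T	C/T	T/T	C/T	T/T	C/T	T/T
12	10954583	A	T	TAS2R7	rs139604652	0.0032	nonsynonymous_SNV	A/T	A/T	A/T	A/T	A/T	A/A	A/T	A/A
12	109617728	A	G	ACACB	rs16940029	0.08	nonsynonymous_SNV	A/G	A/A	A/G	A/A	A/G	A/A	A/G	A/G
16	14029033	G	A	ERCC4	rs1800067	0.03	nonsynonymous_SNV	A/G	G/G	A/G	A/G	A/G	G/G	G/G	A/G
16	15818842	A	G	MYH11	rs16967510	0.02	nonsynonymous_SNV	A/G	A/A	A/G	A/A	A/G	A/G	A/A	A/G
16	22826046	T	G	HS3ST2	rs189013090	0.01	nonsynonymous_SNV	G/T	T/T	G/T	G/T	G/T	T/T	T/T	G/T
17	62028920	C	G	SCN4A	rs41280102	0.01	nonsynonymous_SNV	C/G	C/C	C/G	C/C	C/G	G/G	C/G	C/G
18	67721492	G	C	RTTN	rs34717557	0.01	nonsynonymous_SNV	C/G	G/G	C/G	G/G	C/G	C/G	G/G	C/G
18	67836115	G	T	RTTN	rs34353615	0.01	nonsynonymous_SNV	G/T	G/G	G/T	G/G	G/T	G/T	G/G	G/T
18	72343156	A	G	ZNF407	rs75994611	0.01	nonsynonymous_SNV	A/G	A/A	A/G	A/A	A/G	A/G	A/A	A/G
19	3834863	C	T	ZFR2	rs61747120	0.04	nonsynonymous_SNV	C/T	C/C	C/T	C/C	C/T	C/T	C/T	C/T
22	30733787	C	T	SF3A1	.	.	nonsynonymous_SNV	C/T	C/T	C/T	C/T	C/T	C/T	C/T	C/C
22	30951208	C	T	GAL3ST1	rs139452633	0.0005	nonsynonymous_SNV	C/T	C/T	C/T	C/T	C/T	C/T	C/T	C/C
22	38111897	C	T	TRIOBP	rs143157673	0.0018	nonsynonymous_SNV	C/T	C/T	C/T	C/T	C/T	C/T	C/T	C/C
22	46653273	C	T	PKDREJ	rs147180698	.	nonsynonymous_SNV	C/T	C/C	C/T	C/C	C/T	C/T	C/T	C/C
X	107844666	G	T	COL4A5	rs34077552	0.01	nonsynonymous_SNV	G/T	G/G	G/T	G/T	T/T	G/T	G/T	G/T
X	119293216	-	G	RHOXF2	.	.	other	-/G	-/-	-/G	-/G	-/G	-/G	-/G	-/G
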