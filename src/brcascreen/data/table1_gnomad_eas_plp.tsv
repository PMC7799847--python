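Chr	Start	End	Ref	Alt	Gene.refGene	Func.refGene	AAChange	Clinvar	InterVar	3.5KJPN	gnomAD_EAS
13	32890557	32890558	AG	-	BRCA2	splicing	NA	Likely_pathogenic	Uncertain significance	.	1.09.E-04
13	32890627	32890627	-	T	BRCA2	frameshift insertion	p.T10fs	Pathogenic	Pathogenic	.	6.41.E-04
13	32905124	32905127	GACA	-	BRCA2	frameshift deletion	p.V250fs	Pathogenic	Pathogenic	.	5.44.E-05
13	32906565	32906565	-	A	BRCA2	frameshift insertion	p.T317fs	Pathogenic	Pathogenic	.	5.87.E-05
13	32907014	32907014	A	T	BRCA2	stopgain	p.K467X	Pathogenic	Pathogenic	.	5.53.E-05
13	32910831	32910831	C	G	BRCA2	stopgain	p.S780X	Pathogenic	Pathogenic	.	5.44.E-05
13	32910932	32910932	C	-	BRCA2	frameshift deletion	p.P814fs	Pathogenic	Pathogenic	.	5.51.E-05
13	32911601	32911601	C	T	BRCA2	stopgain	p.Q1037X	Pathogenic	Pathogenic	.	5.45.E-05
13	32911659	32911662	AAAA	-	BRCA2	frameshift deletion	p.Q1056fs	Pathogenic	Pathogenic	.	5.48.E-05
13	32912090	32912091	TG	-	BRCA2	frameshift deletion	p.C1200fs	Pathogenic	Pathogenic	.	5.44.E-05
13	32912234	32912237	AGTG	-	BRCA2	frameshift deletion	p.S1248fs	Pathogenic	Pathogenic	.	5.47.E-05
13	32913656	32913657	AG	-	BRCA2	frameshift deletion	p.S1722fs	Pathogenic	Pathogenic	.	6.42.E-04
13	32914066	32914069	AATT	-	BRCA2	frameshift deletion	p.T1858fs	Pathogenic	Pathogenic	0.0003	5.51.E-05
13	32914137	32914137	C	A	BRCA2	stopgain	p.S1882X	Pathogenic	Pathogenic	.	5.45.E-05
13	32914172	32914172	-	A	BRCA2	stopgain	p.Y1894_E1895delinsX	Pathogenic	Pathogenic	.	5.44.E-05
13	32914356	32914356	C	A	BRCA2	stopgain	p.S1955X	Pathogenic	Pathogenic	.	1.00.E-04
13	32914976	32914977	AA	-	BRCA2	frameshift deletion	p.K2162fs	Pathogenic	Pathogenic	.	5.77.E-05
13	32929367	32929370	AAAC	-	BRCA2	frameshift deletion	p.K2459fs	Pathogenic	Pathogenic	.	5.44.E-05
13	32930609	32930609	C	T	BRCA2	stopgain	p.R2494X	Pathogenic	Pathogenic	.	1.63.E-04
13	32931957	32931957	-	A	BRCA2	frameshift insertion	p.D2566fs	Pathogenic	Pathogenic	.	5.44.E-05
13	32937315	32937315	G	T	BRCA2	splicing	NA	Pathogenic/Likely_pathogenic	Pathogenic	.	6.41.E-04
13	32937362	32937362	A	G	BRCA2	nonsynonymous SNV	p.I2675V	Pathogenic/Likely_pathogenic	Likely pathogenic	0.0001	5.44.E-05
13	32913569	32913569	-	T	BRCA2	frameshift insertion	p.L1693fs	UNK	Likely pathogenic	.	5.71.E-05
13	32930651	32930651	G	A	BRCA2	nonsynonymous SNV	p.G2508S	Conflicting	Likely pathogenic	0.0003	2.26.E-03
13	32930727	32930727	C	T	BRCA2	nonsynonymous SNV	p.S2533F	UNK	Likely pathogenic	.	5.44.E-05
13	32932057	32932057	A	C	BRCA2	nonsynonymous SNV	p.E2599A	UNK	Likely pathogenic	.	5.44.E-05
13	32936755	32936755	T	A	BRCA2	nonsynonymous SNV	p.M2634K	UNK	Likely pathogenic	.	5.44.E-05
13	32937581	32937581	G	C	BRCA2	nonsynonymous SNV	p.G2748R	UNK	Likely pathogenic	.	5.44.E-05
13	32944557	32944557	C	T	BRCA2	nonsynonymous SNV	p.R2784W	Conflicting	Likely pathogenic	.	5.44.E-05
13	32944563	32944563	G	A	BRCA2	nonsynonymous SNV	p.A2786T	Conflicting	Likely pathogenic	0.0001	7.52.E-04
13	32953474	32953474	G	T	BRCA2	nonsynonymous SNV	p.Q2925H	UNK	Likely pathogenic	.	5.45.E-05
13	32953617	32953617	G	A	BRCA2	nonsynonymous SNV	p.R2973H	Conflicting	Likely pathogenic	.	1.64.E-04
13	32968844	32968844	A	G	BRCA2	nonsynonymous SNV	p.Y3092C	Conflicting	Likely pathogenic	.	5.02.E-05
13	32969032	32969032	T	-	BRCA2	frameshift deletion	p.F3155fs	UNK	Likely pathogenic	.	6.42.E-04
17	41201209	41201209	G	-	BRCA1	frameshift deletion	p.Q1779fs	Pathogenic	Pathogenic	.	5.44.E-05
17	41209095	41209095	G	A	BRCA1	stopgain	p.R1751X	Pathogenic	Uncertain significance	.	5.01.E-05
17	41215948	41215948	G	A	BRCA1	nonsynonymous SNV	p.R1699W	Pathogenic	Uncertain significance	.	5.44.E-05
17	41244106	41244106	C	-	BRCA1	frameshift deletion	p.E1148fs	Pathogenic	Pathogenic	.	5.44.E-05
17	41245115	41245115	G	-	BRCA1	frameshift deletion	p.P811fs	Pathogenic	Pathogenic	.	5.44.E-05
17	41256190	41256190	G	T	BRCA1	stopgain	p.Y130X	Pathogenic	Pathogenic	.	5.44.E-05
17	41276080	41276080	G	A	BRCA1	stopgain	p.Q12X	Pathogenic	Pathogenic	.	5.44.E-05
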