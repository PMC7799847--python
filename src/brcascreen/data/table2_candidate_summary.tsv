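Class	Chr	Start	End	Ref	Alt	Gene.refGene	Func.refGene	AAChange	InterVar	Clinvar	3.5KJPN	CADD	Eigen	OncoKB	BRCA_Exchange
InterVar P or LP	13	32903605	32903606	TG	-	BRCA2	frameshift deletion	p.T219fs	P	P	0.0001	.	.	NA	No data
InterVar P or LP	13	32911577	32911577	-	T	BRCA2	frameshift insertion	p.M1029fs	LP	UNK	0.0001	.	.	NA	No data
InterVar P or LP	13	32913262	32913263	GT	-	BRCA2	frameshift deletion	p.K1590fs	LP	UNK	0.0001	.	.	NA	No data
InterVar P or LP	13	32914066	32914069	AATT	-	BRCA2	frameshift deletion	p.T1858fs	P	P	0.0003	.	.	NA	Pathogenic
InterVar P or LP	13	32914210	32914211	CT	-	BRCA2	frameshift deletion	p.N1906fs	P	P	0.0001	.	.	NA	No data
InterVar P or LP	13	32914894	32914898	TAACT	-	BRCA2	frameshift deletion	p.N2134fs	P	P	0.0001	.	.	NA	No data
InterVar P or LP	13	32920978	32920978	C	T	BRCA2	stopgain	p.R2318X	P	P	0.0003	46	0.506	NA	Pathogenic
InterVar P or LP	13	32930651	32930651	G	A	BRCA2	nonsynonymous SNV	p.G2508S	LP	Conflicting	0.0003	34	0.924	Likely Neutral	Not reviewed
InterVar P or LP	13	32930714	32930714	G	-	BRCA2	frameshift deletion	p.G2529fs	LP	UNK	0.0001	.	.	NA	No data
InterVar P or LP	13	32936719	32936719	A	C	BRCA2	nonsynonymous SNV	p.N2622T	LP	UNK	0.0001	28.7	0.965	NA	No data
InterVar P or LP	13	32937362	32937362	A	G	BRCA2	nonsynonymous SNV	p.I2675V	LP	P/LP	0.0001	25.9	0.756	Likely Oncogenic	Not reviewed
InterVar P or LP	13	32944563	32944563	G	A	BRCA2	nonsynonymous SNV	p.A2786T	LP	Conflicting	0.0001	28	0.585	Likely Oncogenic	Not reviewed
InterVar P or LP	13	32944612	32944612	C	T	BRCA2	nonsynonymous SNV	p.P2802L	LP	UNK	0.0003	32	0.291	NA	Not reviewed
InterVar P or LP	13	32954267	32954267	G	A	BRCA2	nonsynonymous SNV	p.V3081I	LP	UNK	0.0001	23.8	-0.348	NA	Not reviewed
InterVar P or LP	17	41197729	41197729	T	C	BRCA1	nonsynonymous SNV	p.Y1853C	LP	LP	0.0003	27	0.694	Likely Oncogenic	Not reviewed
InterVar P or LP	17	41215947	41215947	C	T	BRCA1	nonsynonymous SNV	p.R1699Q	LP	Conflicting	0.0003	35	0.871	Likely Oncogenic	Not reviewed
InterVar P or LP	17	41223120	41223120	T	A	BRCA1	nonsynonymous SNV	p.Q1604L	LP	UNK	0.0001	18.26	-0.385	NA	No data
InterVar P or LP	17	41226421	41226421	-	A	BRCA1	frameshift insertion	p.V1534fs	LP	UNK	0.0001	.	.	NA	No data
InterVar P or LP	17	41228562	41228562	T	C	BRCA1	nonsynonymous SNV	p.K1476R	LP	UNK	0.0001	23.1	0.12	NA	No data
InterVar P or LP	17	41244334	41244334	G	-	BRCA1	stopgain	p.L1072X	P	P	0.0001	.	.	NA	Pathogenic
InterVar P or LP	17	41244748	41244748	G	A	BRCA1	stopgain	p.Q934X	P	P	0.0001	35	0.501	NA	Pathogenic
InterVar P or LP	17	41258497	41258497	A	T	BRCA1	stopgain	p.L63X	P	P	0.0003	39	0.807	NA	Pathogenic
Computational+MAF	13	32900706	32900706	G	T	BRCA2	nonsynonymous SNV	p.S196I	VUS	VUS	0.0003	29.8	0.783	Likely Oncogenic	Not reviewed
Computational+MAF	13	32930669	32930669	A	G	BRCA2	nonsynonymous SNV	p.K2514E	VUS	VUS	0.0001	32	0.865	NA	Not reviewed
Computational+MAF	13	32944605	32944605	C	T	BRCA2	nonsynonymous SNV	p.P2800S	VUS	VUS	0.0001	33	0.864	NA	Not reviewed
Computational+MAF	13	32968948	32968948	T	G	BRCA2	nonsynonymous SNV	p.W3127G	VUS	UNK	0.0001	29.3	0.764	NA	No data
Computational+MAF	17	41197783	41197783	C	T	BRCA1	nonsynonymous SNV	p.R1835Q	VUS	VUS	0.0001	34	0.738	Likely Oncogenic	Not reviewed
Computational+MAF	17	41215957	41215957	C	T	BRCA1	nonsynonymous SNV	p.V1696M	VUS	VUS	0.0001	33	0.754	Likely Oncogenic	Not reviewed
Computational+MAF	17	41256212	41256212	G	A	BRCA1	nonsynonymous SNV	p.S123F	VUS	UNK	0.0001	28.2	0.686	NA	Not reviewed
Benign	13	32913077	32913077	G	A	BRCA2	nonsynonymous SNV	p.G1529R	Benign	Likely benign	0.0001	.	.	NA	Benign / Little Clinical Significance
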