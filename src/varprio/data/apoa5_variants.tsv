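gene	exon	cdna	protein	rsid	status	sift	polyphen_hdiv	lrt	mutation_taster	mutation_assessor	cadd	af_all	af_eas	af_amr	phylo_hmm	n_het_hlap	n_hom_hlap	n_het_bap	n_hom_bap
APOA5	exon2	c.104G>A	p.S35N	rs184390502	known	D	P	N	N	M	21	5.35E-05	6.69E-04	0.0	0.046	1	0	0	0
APOA5	exon3	c.500A>T	p.D167V	rs762999453	known	D	B	N	D	M	20.9	4.00E-06	5.45E-05	0.0	0.419	1	0	0	0
APOA5	exon3	c.553G>T	p.G185C	rs2075291	known	D	D	N	N	M	24.5	6.23E-03	6.77E-02	2.83E-04	-0.055	42	7	1	0
APOA5	exon3	c.563A>T	p.K188I	na	novel	D	P	N	N	M	22.2	na	na	na	-0.033	1	0	0	0
APOA5	exon3	c.667C>T	p.R223C	na	novel	D	D	D	D	M	29	na	na	na	0.419	1	0	0	0
APOA5	exon3	c.544_545insGGTGC	p.H182fs	na	novel	na	na	na	na	na	na	na	na	na	na	1	0	0	0
APOA5	exon2	c.77G>T	p.G26V	rs548745995	known	T	P	N	D	M	24	4.15E-06	5.62E-05	0.0	0.514	0	0	1	0
APOA5	exon3	c.457G>A	p.V153M	rs3135507	known	T	B	N	P	L	3.66	5.09E-02	1.19E-01	4.59E-02	0.43	47	5	10	1
APOA5	exon3	c.538G>C	p.V180L	rs753800578	known	T	B	N	N	M	17.37	2.41E-05	3.29E-04	0.0	-0.042	0	0	1	0
APOA5	exon3	c.788G>A	p.G263D	na	novel	T	B	N	N	L	1.838	na	na	na	-0.042	1	0	0	0
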