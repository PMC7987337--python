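patient_id	nucleotide_change	aa_change	dbsnp	consequence	cadd	nfe_af	function	clinical_category	age	cohort
P1	c.655G>A	Val219Ile	rs149314023	missense	12.28	0.0003	HYPO	4	32	Italian
P2	c.863C>T	Ala288Val	rs200146658	missense	15.37	0.000012	Neutral	3	57	Italian
P3	c.901T>C	Ser301Pro		missense	26.4		LOF	3	46	Italian
P4	c.1343C>T	Ala448Val	rs5743781	missense	13.08	0.00465	Neutral	3	53	Italian
P5	c.1343C>T	Ala448Val	rs5743781	missense	13.08	0.00465	Neutral	3	58	Italian
P6	c.2759G>A	Arg920Lys	rs189681811	missense	16.52	0.0002	LOF	4	49	Italian
P7	c.3094G>A	Ala1032Thr	rs147244662	missense	22.3	0.0006	LOF	3	65	Italian
P8	c.3094G>A	Ala1032Thr	rs147244662	missense	22.3	0.0006	LOF	3	66	Italian
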