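cdna	aa	fold_increase	pssm	mupro	sdm	psa_mc	psa_sc	sec_stru	domain	active_site	phenotype	responsive
c.688G>A	p.A230T	2.1	0	-2.33	-0.48	4	64.8	P(5)	TIM	Yes	Classic	No
c.730G>C	p.D244H	3.3	-1	-1.74	0.379	18.6	48.7	A(11)	TIM	No	Classic	Yes
c.805G>A	p.V269M	2.5	0	-0.77	-0.212	3.2	0	O(12)	TIM	No	Classic	Yes
c.838C>A	p.Q280K	3.1	0	-1.00	-1.126	0	17.3	A(14)	TIM	No	Classic	Yes
c.898C>T	p.L300F	5.8	-1	-1.60	-0.732	9.9	0	O(6)	TIM	No	NA	Yes
c.902G>C	p.R301P	3.7	-1	-1.68	-1.228	65.2	17.5	O(6)	TIM	No	Classic	Yes
c.928C>T	p.L310F	8.9	0	-1.34	-1.334	1.7	5.1	A(5)	TIM	No	Classic	Yes
c.1023A>C	p.E341D	2.2	-1	-0.88	-1.055	0	0	B(9)	beta	No	Classic	No
c.1228A>G	p.T410A	3.5	-1	-1.47	0.215	0	0	O(1)	beta	No	Variant	Yes
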