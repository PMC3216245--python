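cdna	aa	pssm	mupro	sdm	psa_mc	psa_sc	sec_stru	domain	active_site	responsive
c.58G>C	p.A20P	-2	-2.00	NA	NA	NA	NA	leader peptide	No	Yes
c.153G>A	p.M51I	-2	-0.51	0.414	0.0	27.1	O(15)	TIM	No	Yes
c.155G>A	p.C52Y	-5	-1.37	-1.582	29.5	27.3	O(15)	TIM	No	No
c.194G>C	p.S65T	-1	-0.85	0.330	0.0	25.5	O(15)	TIM	No	Yes
c.214A>G	p.M72V	-1	-0.27	-1.232	0.0	0.0	A(10)	TIM	No	Yes
c.426C>G	p.C142W	-7	-0.91	0.167	64.6	33.8	O(15)	TIM	Yes	No
c.436C>T	p.P146S	-3	-0.44	-0.983	1.4	19.5	O(15)	TIM	No	Yes
c.467C>T	p.A156V	-1	-0.26	-0.357	0.0	0.6	A(11)	TIM	No	Yes
c.496C>G	p.L166	0	-1.18	-0.244	0.0	3.9	B(5)	TIM	No	Yes
c.548G>C	p.G183A	-2	-0.85	2.330	1.5	5.3	A(18)	TIM	No	Yes
c.581C>T	p.T194I	-2	-0.57	2.008	76.0	2.6	A(18)	TIM	No	Yes
c.647A>G	p.Y216C	-3	-1.16	-2.319	11.3	1.9	A(6)	TIM	No	Yes
c.692A>G	p.D231G	-2	-2.24	-2.726	49.3	66.7	P(5)	TIM	Yes	No
c.796G>A	p.D266N	-3	-1.30	-0.754	12.8	4.4	O(12)	TIM	No	No
c.868A>C	p.M290L	0	-0.18	0.486	0.5	2.9	A(14)	TIM	No	Yes
c.890C>T	p.S297F	-3	-0.73	2.714	0.0	0.0	B(7)	TIM	Yes	No
c.1118G>A	p.G373D	-3	-0.98	0.251	0.5	0.3	O(12)	beta	No	No
c.1117G>A	p.G373S	-3	-1.18	-0.256	0.5	0.3	O(12)	beta	No	No
c.1244T>C	p.L415P	-2	-2.06	-1.232	0.0	0.7	B(9)	beta	No	No
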