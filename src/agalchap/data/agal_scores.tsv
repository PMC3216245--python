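pos	wt	mut	score
20	A	P	-2
51	M	I	-2
52	C	Y	-5
65	S	T	-1
72	M	V	-1
142	C	W	-7
146	P	S	-3
156	A	V	-1
183	G	A	-2
194	T	I	-2
216	Y	C	-3
230	A	T	0
231	D	G	-2
244	D	H	-1
266	D	N	-3
269	V	M	0
280	Q	K	0
290	M	L	0
297	S	F	-3
300	L	F	-1
301	R	P	-1
310	L	F	0
341	E	D	-1
373	G	D	-3
373	G	S	-3
410	T	A	-1
415	L	P	-2
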