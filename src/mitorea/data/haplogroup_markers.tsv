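haplogroup	position	ref	alt
H	263	A	G
H	750	A	G
H	1438	A	G
H	4769	A	G
H	8860	A	G
H	15326	A	G
J	295	C	T
J	489	T	C
J	10398	A	G
J	12612	A	G
J	13708	G	A
J	16069	C	T
J	16126	T	C
T	709	G	A
T	1888	G	A
T	4917	A	G
T	8697	G	A
T	10463	T	C
T	13368	G	A
T	15607	A	G
T	16294	C	T
U	11467	A	G
U	12308	A	G
U	12372	G	A
K	1811	A	G
K	9055	G	A
K	10550	A	G
K	11467	A	G
K	12308	A	G
K	12372	G	A
K	14167	C	T
K	16224	T	C
K	16311	T	C
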