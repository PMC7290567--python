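haplogroup	parent	variants
L3	-	7363A>G,9407A>T,15110A>G
M	L3	613T>A,10504C>A
N	L3	7374C>A,10348C>T
M7	M	13288T>C,14926A>C
M7b1	M7	2448A>C,3654C>T
M7c1	M7	1056T>G,13956T>A
R	N	5107C>T,10848C>G
F4a	R	6446T>C,11225G>C,15988A>C
K	R	7183G>A,11442C>A
K1a	K	7390C>T,11324G>T
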