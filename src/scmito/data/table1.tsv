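Protocol	All	Common	Hom	Het	%Common	Unique	Confirmed	%Confirmed
DOP	41	37	31	6	90.24	4	33	89.19
eWGA	44	40	37	3	90.91	4	36	90
MALBAC	3	3	2	1	100	0	2	66.67
MDA	43	38	36	2	87.37	5	36	94.74
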