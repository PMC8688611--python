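nuclide	half_life_value	half_life_unit	stable	daughter	branching	emission_class
Ac-225	9.92	d	0	Fr-221	1.0	alpha
Fr-221	4.80	min	0	At-217	1.0	gamma-accompanied-alpha
At-217	32.3	ms	0	Bi-213	1.0	alpha
Bi-213	45.6	min	0	Po-213	0.978	gamma-accompanied-beta
Bi-213	45.6	min	0	Tl-209	0.022	alpha
Po-213	3.7	us	0	Pb-209	1.0	alpha
Tl-209	2.16	min	0	Pb-209	1.0	gamma-accompanied-beta
Pb-209	3.23	h	0	Bi-209	1.0	beta
Bi-209	0	-	1	-	-	-
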