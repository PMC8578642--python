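species_id	is_parasite	clade	reference_clade
u01	0	A	root
u02	0	A	root
u03	0	A	root
u04	0	A	root
u05	0	A	root
u06	0	A	root
u07	0	B	root
u08	0	B	root
u09	0	B	root
u10	0	B	root
u11	1	B	root
u12	1	B	root
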