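S01	size2-dropped	t01	t02
S02	triple	t01	t02	t03
S03	quad	t04	t05	t06	t07
S04	quint	t08	t09	t10	t11	t12
S05	cross	t01	t04	t08
S06	size51-dropped	x01	x02	x03	x04	x05	x06	x07	x08	x09	x10	x11	x12	x13	x14	x15	x16	x17	x18	x19	x20	x21	x22	x23	x24	x25	x26	x27	x28	x29	x30	x31	x32	x33	x34	x35	x36	x37	x38	x39	x40	x41	x42	x43	x44	x45	x46	x47	x48	x49	x50	x51
S07	size50-kept	y01	y02	y03	y04	y05	y06	y07	y08	y09	y10	y11	y12	y13	y14	y15	y16	y17	y18	y19	y20	y21	y22	y23	y24	y25	y26	y27	y28	y29	y30	y31	y32	y33	y34	y35	y36	y37	y38	y39	y40	y41	y42	y43	y44	y45	y46	y47	y48	y49	y50
S08	triple	t13	t14	t15
S09	triple	t16	t17	t18
S10	size2-dropped	t03	t04
S11	six	t01	t02	t03	t04	t05	t06
S12	triple	t19	t20	t01
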