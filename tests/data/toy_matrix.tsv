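	u01	u02	u03	u04	u05	u06	u07	u08	u09	u10	u11	u12
t01	1	1	1	1	1	1	1	1	1	1	1	1
t02	1	1	1	1	1	1	1	1	1	1	1	1
t03	1	1	1	1	1	1	1	1	1	1	1	1
t04	1	1	1	1	1	1	1	1	1	1	1	1
t05	1	1	1	1	1	1	1	1	1	1	1	1
t06	1	1	1	1	1	1	1	1	1	1	0	0
t07	1	1	1	1	1	1	1	1	1	1	0	0
t08	1	1	1	1	1	1	1	1	1	1	0	0
t09	1	1	1	1	1	1	1	1	1	0	1	0
t10	1	1	1	1	1	1	0	0	0	0	0	0
t11	1	1	1	1	1	1	0	0	0	0	0	0
t12	1	1	1	1	1	1	0	0	0	0	0	0
t13	1	1	1	1	1	1	0	0	0	0	0	0
t14	1	1	1	1	1	1	0	0	0	0	0	0
t15	1	1	1	1	1	1	0	0	0	0	0	0
t16	1	1	1	1	1	1	1	1	0	0	0	0
t17	1	1	1	1	1	1	1	1	0	0	0	0
t18	1	1	1	1	1	1	1	1	0	0	0	0
t19	1	1	1	1	1	1	1	1	0	0	0	0
t20	1	1	1	1	1	1	1	1	0	0	0	0
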