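name	n_genomes	steppe_prop	calbp_early	calbp_late	calbp_mean	x_m	y_m
Esperstedt_MN	1	0.00	5310	5036	5173	5500000	1300000
HungaryGamba_CA	1	0.00	4853	4756	4805	5500000	2300000
Corded_Ware_LN	5	0.78	4731	4255	4493	5600000	1300000
Karsdorf_LN	1	0.73	4514	4425	4470	5500000	1400000
Alberstedt_LN	2	0.56	4427	4295	4361	5600000	1400000
Bell_Beaker_LN	10	0.47	4305	4186	4245	5700000	1300000
Benzigerode_LN	3	0.57	4208	4095	4151	5600000	1200000
Unetice_EBA	8	0.43	4069	3926	3998	5700000	1400000
HungaryGamba_BA	2	0.15	3680	3582	3631	5400000	2200000
Halberstadt_LBA	1	0.55	3063	2971	3017	5700000	1200000
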