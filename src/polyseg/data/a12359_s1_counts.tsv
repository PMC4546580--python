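marker	AA	Aa	aa	missing	chi2_disomic	p_disomic	chi2_tetrasomic	p_tetrasomic
CDCA5-491/492	67	126	73	7	1.01	0.6	1106.32	<0.01
CDCA7-623/624	60	154	54	5	6.24	0.04	694.54	<0.01
CDGA1-783/784	57	152	62	2	4.2	0.12	764.98	<0.01
CDGA3-1195/1196	62	125	70	16	0.69	0.71	1021.85	<0.01
CDGA6-1583/1584	47	152	65	9	8.51	0.01	686.65	<0.01
CDGA7-1601/1602	4	195	66	8	87.97	<0.01	470.03	<0.01
CDGA8-1795/1796	70	143	58	2	1.89	0.39	910.75	<0.01
CDATG1-1889/1890	66	117	83	7	6.02	0.05	1287.87	<0.01
CDATG3-1999/2000	59	145	59	10	2.77	0.25	750.05	<0.01
CDAAC5-2523/2524	66	139	67	1	0.14	0.93	982.51	<0.01
CDAAC7-2675/2676	67	141	59	6	1.32	0.52	874.56	<0.01
CDAAC7-2693/2694(1)	103	117	43	10	30.57	<0.01	1453.26	<0.01
CDAAC7-2693/2694(2)	14	168	90	1	57.53	<0.01	943.95	<0.01
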