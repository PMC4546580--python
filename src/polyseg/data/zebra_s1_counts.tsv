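marker	AA	Aa	aa	missing	chi2_disomic	p_disomic	chi2_tetrasomic	p_tetrasomic
CDCA1-21/22	16	183	28	1	86.38	<0.01	94.28	<0.01
CDCA2-231/232	39	111	77	1	12.38	<0.01	1013.01	<0.01
CDCA3-247/248	50	147	28	3	25.46	<0.01	402.13	<0.01
CDCA3-313/314	10	132	86	0	56.35	<0.01	1042.73	<0.01
CDCA4-323/324	16	156	47	9	48.27	<0.01	309.40	<0.01
CDCA7-653/654	39	110	77	2	12.94	<0.01	1013.24	<0.01
CDCA7-693/694	13	120	93	2	57.50	<0.01	1241.16	<0.01
CDCA8-737/738	31	146	47	4	22.93	<0.01	388.03	<0.01
CDGA1-847/848	37	135	56	0	10.90	<0.01	571.69	<0.01
CDGA1-921/922	52	100	73	3	6.70	0.04	1107.34	<0.01
CDGA1-929/930	8	161	52	7	63.68	<0.01	356.91	<0.01
CDGA3-1103/1104	10	173	42	3	74.17	<0.01	214.08	<0.01
CDGA4-1245/1246	36	184	7	1	94.99	<0.01	144.40	<0.01
CDGA5-1427/1428	60	153	15	0	44.45	<0.01	487.82	<0.01
CDGA7-1611/1612	0	172	56	0	86.53	<0.01	407.12	<0.01
CDGA8-1765/1766	48	117	61	2	1.78	0.41	794.50	<0.01
CDGA8-1807/1808	44	117	61	6	3.25	0.19	755.73	<0.01
CDATG6-2123/2124	9	145	71	3	52.95	<0.01	693.46	<0.01
CDATG6-2143/2144	57	154	15	2	45.36	<0.01	436.56	<0.01
CDAAC7-2703/2704	37	161	28	2	41.50	<0.01	237.21	<0.01
CDCAG3-2897/2898	1	174	51	2	87.98	<0.01	328.89	<0.01
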