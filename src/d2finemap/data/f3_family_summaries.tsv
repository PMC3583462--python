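f2_id	batch	n	median_cm	mean_cm	sd_cm	n_below_110
1	1	23	85	87	13.99	23
55	1	23	139	137.6	22.63	3
177	1	23	62	63	11.82	23
263	1	25	104	109.1	16.94	NA
310	1	25	160	155.4	22.66	0
320	1	24	150.5	150.5	21.57	0
344	1	23	85	86	17.20	21
349	NA	NA	NA	NA	NA	NA
374	2	23	89	82.3	18.16	NA
477	1	25	61	64.8	16.04	25
479	1	22	155	153	29.27	1
486	1	24	107	109.6	30.09	NA
486	3	15	130	121.8	23.21	NA
496	1	23	142	132.5	28.17	4
514	2	21	121	129.9	34.66	NA
612	2	23	154	150.3	24.35	2
701	2	15	181	179.8	23.63	0
778	2	21	145	145.1	26.81	1
787	3	17	157	150.7	26.51	2
812	2	17	210	203.2	22.54	0
900	2	13	189	182	23.88	0
914	2	14	192.5	185.9	47.83	2
924	2	22	186	186.4	24.49	0
930	2	18	206	208.4	28.34	0
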