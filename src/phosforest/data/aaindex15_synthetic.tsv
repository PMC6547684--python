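#index	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
BLAM930101	0.96	0.77	0.39	0.42	0.42	0.80	0.53	0.00	0.57	0.84	0.92	0.73	0.86	0.59	-2.50	0.53	0.54	0.58	0.72	0.63
MAXF760101	1.43	1.18	0.64	0.92	0.94	1.22	1.67	0.46	0.98	1.04	1.36	1.27	1.53	1.19	0.49	0.70	0.78	1.01	0.69	0.98
TSAJ990101	89.3	190.3	122.4	114.4	102.5	146.9	138.8	63.8	157.5	163.0	163.1	165.1	165.8	190.8	121.6	94.2	119.6	226.4	194.6	138.2
NAKH920108	9.36	3.76	3.25	2.85	2.35	2.88	3.10	8.51	1.72	8.25	12.30	2.82	3.73	7.92	3.13	5.58	4.68	2.54	3.54	9.53
CEDJ970104	7.9	4.9	4.0	5.5	1.9	4.4	7.1	7.1	2.1	5.2	8.6	6.7	2.4	3.9	5.3	6.6	5.3	1.2	3.1	6.8
LIFS790101	0.92	0.93	0.60	0.48	1.16	0.95	0.61	0.61	0.93	1.81	1.30	0.70	1.19	1.25	0.40	0.82	1.12	1.54	1.53	1.81
NOZY710101	0.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.5	1.8	1.8	0.0	1.3	2.5	0.0	0.0	0.4	3.4	2.3	1.5
HUTJ700103	154.33	341.01	207.90	194.91	219.79	235.51	223.16	127.90	242.54	233.21	232.30	300.46	202.65	204.74	179.93	174.06	205.80	237.01	229.15	207.60
NAKH900109	8.63	5.00	4.30	5.20	1.90	4.10	6.20	7.40	2.20	5.50	9.00	5.70	2.30	4.00	5.00	6.90	5.80	1.30	3.20	6.50
BIOV880101	16	-70	-74	-78	168	-73	-106	-13	50	151	145	-141	124	189	-20	-70	-38	145	53	123
MIYS990104	-0.04	0.07	0.13	0.19	-0.38	0.14	0.23	0.09	-0.04	-0.34	-0.37	0.33	-0.30	-0.38	0.19	0.12	0.03	-0.33	-0.29	-0.29
PUNT030101	1.00	0.50	0.60	0.50	1.20	0.60	0.50	1.00	0.80	1.50	1.40	0.40	1.30	1.40	0.60	0.90	0.90	1.10	1.00	1.50
WOEC730101	7.0	9.1	10.0	13.0	5.5	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5.0	6.6	7.5	6.6	5.2	5.4	5.6
BASU050102	0.07	0.04	0.03	0.02	0.13	0.04	0.03	0.05	0.06	0.14	0.14	0.01	0.12	0.15	0.03	0.04	0.05	0.13	0.10	0.12
SUYM030101	1.00	1.10	1.00	1.10	0.70	1.20	1.10	1.10	1.10	0.80	0.90	1.00	1.00	0.90	1.60	1.10	1.10	0.80	0.90	0.80
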