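gene	pathway	GL	TQ	93-11	GLxTQ	GLx93-11	93-11xTQ
OsPRR1	flowering	35.49	92.53	122.96	122.26	89.91	138.95
RFT1	flowering	2.28	0.16	0.43	1.45	0.48	0.20
Hd3a	flowering	1.33	0.00	0.00	0.21	0.00	0.00
Hd1	flowering	0.57	3.27	1.30	2.17	5.82	1.62
Ghd7	flowering	0	0	0.30	0	0.64	0.18
Ehd2	flowering	2.05	0.83	0.22	1.08	0.81	0.32
Ehd1	flowering	2.63	0	0	0	0	0
OsCPS1	ga_metabolism	0.23	0.46	0.71	0.92	0.50	0.67
OsKAO	ga_metabolism	0.07	0.61	0.66	0.95	1.17	0.61
OsGA3ox2	ga_metabolism	2.12	0.10	0.22	0.80	0.46	0.92
OsGA20ox2	ga_metabolism	12.92	3.15	4.84	9.36	5.78	5.51
OsGA2ox6	ga_metabolism	0.82	5.43	1.12	4.54	8.37	7.95
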