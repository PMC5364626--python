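gene	fc_48h_siA	fc_48h_siC	fc_120h_siA	fc_120h_siC
LEP	4.51	16.62	29.16	23.41
AC005863.1	3.35	3.90	9.60	5.55
OLFML2A	1.71	2.55	8.02	2.71
SESN3	2.98	2.01	6.80	2.53
TNS1	2.66	4.73	6.43	6.12
NEK7	2.42	2.30	5.67	3.95
MAN1A1	1.82	2.03	5.26	2.67
MAF	2.81	4.89	4.56	5.47
BMF	3.81	3.48	4.49	4.49
SCPEP1	1.53	1.56	3.76	1.26
PBXIP1	1.88	2.14	3.49	2.32
CBX1	2.04	2.28	3.01	3.39
ENDOD1	1.80	1.82	2.99	3.04
SGK1	1.63	1.54	2.89	1.93
HSPB1	1.65	1.47	2.75	1.48
RNF152	1.55	1.84	2.55	1.97
SERPINA1	2.85	2.71	2.48	2.79
PGAM1	1.64	1.70	2.47	2.02
ASPH	1.59	1.66	2.44	2.37
MAMDC2	2.56	3.17	2.43	7.40
SHROOM2	1.66	1.95	2.42	1.80
EPHB2	1.55	2.12	2.20	2.63
ITGB6	1.84	2.47	2.19	4.01
IL1R1	2.16	2.02	2.16	1.66
TGFBI	1.99	2.75	2.00	5.83
SLITRK6	1.80	2.11	1.86	2.62
PNRC2	1.63	1.56	1.31	1.36
PHACTR3	0.43	0.53	0.43	0.52
IL8	0.45	0.49	0.42	0.18
CRCT1	0.34	0.54	0.39	0.58
CNOT6	0.59	0.64	0.39	0.56
LIF	0.43	0.41	0.38	0.35
KRT80	0.58	0.38	0.32	0.33
CXCL3	0.43	0.35	0.28	0.20
IL1B	0.52	0.38	0.17	0.33
CXCL5	0.54	0.47	0.17	0.34
IL1A	0.55	0.65	0.09	0.49
IL6	0.33	0.48	0.03	0.20
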