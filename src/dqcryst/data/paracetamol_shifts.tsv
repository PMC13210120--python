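structure	site	species	delta_exp	delta_dft	delta_xrd	overlapped
Para	1OH	1H	9.2	9.79	9.32	0
Para	H2	1H	5.75	5.42	5.31	0
Para	H3	1H	6.6	6.76	6.67	1
Para	H5	1H	7.86	7.95	7.90	0
Para	H6	1H	6.6	6.58	6.48	1
Para	NH	1H	9.03	9.47	9.06	0
Para	CH3	1H	1.07	0.68	0.20	0
Para	C1	13C	152.18	154.21	154.06	0
Para	C2	13C	116.19	116.56	115.82	0
Para	C3	13C	120.48	121.49	121.66	0
Para	C4	13C	132.91	133.33	134.26	0
Para	C5	13C	123.24	124.62	124.36	0
Para	C6	13C	115.64	115.82	115.78	0
Para	CO	13C	169.69	166.50	165.97	0
Para	CH3	13C	23.64	21.43	18.07	0
ParaHCl	1OH	1H	8.2	8.33	-0.99	0
ParaHCl	H2	1H	6.5	6.58	4.24	1
ParaHCl	H3	1H	6.7	6.62	5.00	0
ParaHCl	H5	1H	6.5	6.46	4.01	1
ParaHCl	H6	1H	6.2	6.17	3.36	0
ParaHCl	COH	1H	16.91	17.22	10.86	0
ParaHCl	NH	1H	10.76	10.39	4.24	0
ParaHCl	CH3	1H	2.82	2.56	-1.84	0
ParaHCl	H2AO	1H	7.2	7.21	-2.23	0
ParaHCl	H2BO	1H	6.6	6.58	-0.97	0
ParaHCl	C1	13C	155.79	157.66	157.55	0
ParaHCl	C2	13C	114.66	113.92	107.11	0
ParaHCl	C3	13C	122.23	123.12	117.79	1
ParaHCl	C4	13C	128.22	128.85	128.03	0
ParaHCl	C5	13C	122.23	122.17	116.03	1
ParaHCl	C6	13C	117.54	118.07	113.47	0
ParaHCl	COH	13C	172.43	168.37	169.89	0
ParaHCl	CH3	13C	22.63	19.62	-2.00	0
ParaOA	1OH	1H	8.3	9.23	8.92	0
ParaOA	H2	1H	5.5	5.54	5.31	0
ParaOA	H3	1H	6.5	6.66	6.42	0
ParaOA	H5	1H	7.2	7.39	7.37	1
ParaOA	H6	1H	7.2	7.18	6.85	1
ParaOA	NH	1H	9.3	10.17	10.00	0
ParaOA	CH3	1H	1.99	1.78	1.46	0
ParaOA	HOA1	1H	11.68	12.57	11.06	0
ParaOA	HOAN	1H	14.75	16.39	13.62	0
ParaOA	C1	13C	150.78	154.60	152.61	0
ParaOA	C2	13C	115.05	115.41	110.81	1
ParaOA	C3	13C	120.86	122.50	121.49	1
ParaOA	C4	13C	132.77	133.74	134.02	0
ParaOA	C5	13C	120.86	123.26	123.06	1
ParaOA	C6	13C	115.05	115.03	117.34	1
ParaOA	CO	13C	173.84	173.32	171.12	0
ParaOA	CH3	13C	24.27	21.80	19.92	0
ParaOA	COA1	13C	160.38	162.79	162.01	0
ParaOA	COAN	13C	159.43	161.47	158.85	0
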