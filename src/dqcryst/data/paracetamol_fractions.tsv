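structure	group_j	group_k	f_nmr	f_dft	f_xrd	r_eff_dft	r_eff_nmr_dft	r_eff_xrd	r_eff_nmr_xrd	excluded	motion
Para	1OH.NH	H2	0.029	0.024	0.021	229	220	230	218	0	static
Para	1OH.NH	H3.H6	0.071	0.061	0.057	235	227	235	226	0	static
Para	1OH.NH	CH3	0.074	0.067	0.060	193	188	194	187	0	static
Para	H2	H3.H6	0.034	0.019	0.018	237	214	236	213	0	static
Para	H2	CH3	0.056	0.051	0.043	202	197	205	196	0	static
Para	H3.H6	H5	0.022	0.022	0.020	232	230	233	229	0	static
Para	H3.H6	CH3	0.065	0.039	0.035	211	192	211	191	0	static
Para	H5	H5	0.026	0.030	0.026	221	224	222	222	0	static
Para	H5	CH3	0.012	0.012	0.011	290	287	290	285	0	static
Para	CH3	CH3	0.611	0.675	0.709	177	178	173	177	0	static
ParaHCl	Ar.H2O	Ar.H2O	0.424	0.506	0.632	164	169	144	154	0	static
ParaHCl	Ar.H2O	COH	0.085	0.141	0.078	203	221	205	202	0	static
ParaHCl	Ar.H2O	NH	0.113	0.054	0.033	213	188	211	172	0	static
ParaHCl	Ar.H2O	CH3	0.122	0.098	0.055	260	251	260	228	0	static
ParaHCl	COH	NH	0.010	0.005	0.003	318	301	315	273	0	static
ParaHCl	COH	CH3	0.032	0.039	0.026	225	236	219	214	0	static
ParaHCl	NH	CH3	0.055	0.050	0.030	216	212	213	193	0	static
ParaHCl	CH3	CH3	0.159	0.107	0.143	181	170	157	154	0	fast_3site
ParaOA	Ar.NH	Ar.NH	0.458	0.384	0.404	230	223	222	218	0	static
ParaOA	H5.H6.NH	CH3	0.386	0.578	0.564					1	static
ParaOA	H5.H6	HOAN	0.035	0.047	0.044	314	330	305	317	0	static
ParaOA	CH3	CH3	0.295	0.274	0.294	177	175	168	168	0	fast_3site
ParaOA	CH3	HOA1	0.010	0.017	0.020	332	364	314	354	0	static
ParaOA	CH3	HOAN	0.063	0.112	0.094	242	266	242	259	0	static
ParaOA	HOA1	1OH	0.080	0.099	0.065	220	228	227	219	0	static
ParaOA	HOA1	H2	0.049	0.054	0.057	243	247	232	238	0	static
ParaOA	HOA1	HOAN	0.010	0.013	0.022	309	321	276	312	0	static
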