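variable	oa_mean	oa_sd	nd_mean	nd_sd	nd_n	d_mean	d_sd	d_n	printed_p	printed_stat	test
age_years	67.86	6.46	66.34	5.60	35	68.60	6.77	25	0.147	534	mann_whitney
bmi_kg_m2	25.39	2.96	25.22	3.08	35	26.02	2.66	25	0.298	-1.049	t
cognitive_mmse	28.74	1.38	28.94	1.31	35	28.68	1.49	25	0.495	394	mann_whitney
ipaq_met_min_week	3193.70	2829.86	3186.46	2964.91	35	3519.66	2822.11	25	0.509	393.5	mann_whitney
handgrip_kg	27.39	8.56	36.59	39.86	35	25.07	7.54	25	0.018	279.5	mann_whitney
one_leg_stance_s	30.32	22.77	38.83	20.93	35	18.19	20.72	25	0.001	192.5	mann_whitney
barthel_score	19.86	0.35	19.97	0.17	35	19.76	0.44	25	0.013	345	mann_whitney
lawton_score	22.70	1.23	23.00	0.00	35	21.96	2.67	25	0.002	332.5	mann_whitney
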