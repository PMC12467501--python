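phase	oa_mean	oa_sd	nd_mean	nd_sd	d_mean	d_sd	printed_p	printed_stat	test
tug_total	10.83	2.02	10.34	2.14	11.51	1.63	0.006	254.00	mann_whitney
sit_to_walk	1.36	0.25	1.30	0.27	1.44	0.20	0.015	-2.21	t
walk_forward	2.21	0.48	2.08	0.49	2.39	0.41	0.003	237.00	mann_whitney
turn	1.78	0.32	1.71	0.29	1.87	0.35	0.086	323.00	mann_whitney
walk_back	2.73	0.71	2.56	0.77	2.97	0.55	0.007	259.00	mann_whitney
turn_to_sit	2.72	0.70	2.64	0.76	2.84	0.59	0.060	312.00	mann_whitney
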