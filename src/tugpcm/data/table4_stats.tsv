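component	p_value	u_statistic	cohens_d	ci_low	ci_high
1	0.035	278	0.59	0.06	1.12
2	0.094	306	0.34	-0.18	0.86
3	0.146	320	0.32	-0.85	0.20
4	0.035	278	0.08	-0.44	0.60
5	0.832	399	0.07	-0.45	0.59
6	0.282	344	-0.04	-0.55	0.48
7	0.061	293	0.44	-0.10	0.98
8	0.206	332	-0.32	-0.85	0.21
9	0.179	327	0.37	-0.17	0.91
10	0.783	395	0.06	-0.47	0.59
11	0.906	405	0.12	-0.41	0.66
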