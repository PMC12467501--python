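variable	nd_yes	nd_no	d_yes	d_no	printed_chi2	printed_p	continuity
gender_female	19	16	19	6	2.961	0.085	False
fall_history	11	24	11	14	0.525	0.469	True
polypharmacy	2	33	11	14	12.595	0.001	False
self_reported_health_poor	8	27	21	4	21.832	0.001	False
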