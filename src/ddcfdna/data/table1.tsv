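animal	troponin_ng_per_l	time_to_rejection_days	censored	baseline_fragment_bp	endpoint_fragment_bp	pct_ddcfdna_phased	pct_ddcfdna_unphased
A	434	41	0	2319	3887	2.20	2.55
B	1458	89	0	2167	4258	1.77	1.95
C	11185	33	0	2283	5493	7.23	7.44
D	1144	53	0	3463	4014	2.21	2.51
E	24601	39	0	2701	4587	4.89	4.80
F	526	106	1	2690	3797	2.01	2.22
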