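system	group	site_I	err_I	site_II	err_II	site_III	err_III
E1_S0	wildtype	0.1	0.1	4.5	0.1	1.8	0.1
E1_S1	wildtype	3.7	0.2	1.7	0.1	4.7	0.1
E1_S2	wildtype	-3.5	1.0	3.8	0.3	2.9	0.6
E1_S3	wildtype	-1.5	0.2	4.7	0.4	-0.5	0.3
E2_S0	wildtype	-4.4	0.3	-6.1	0.0
E2_S1	wildtype	-3.5	0.1	-6.1	0.1
P-E2_S0	wildtype	-1.0	0.6	0.7	0.4
E1_S1M	mutant	1.4	0.1	5.7	0.0	2.4	0.1
E1_S2M	mutant	4.3	0.7	6.6	0.6	5.2	0.9
E1_S3M	mutant	-0.6	0.1	1.7	0.1	0.0	0.0
E2_S1M	mutant	-3.3	0.3	-5.7	0.0
E2_S2M	mutant	-5.4	0.1	-6.4	0.1
E2_S3M	mutant	-3.8	0.1	-7.2	0.1
P-E2_S1M	mutant	0.8	0.9	1.9	0.4
P-E2_S2M	mutant	1.6	0.5	1.9	0.4
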