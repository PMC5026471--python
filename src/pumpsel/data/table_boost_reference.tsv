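helix	residue	k1	chi0_1	k2	chi0_2	k3	chi0_3	k4	chi0_4	k5	chi0_5	k6	chi0_6
M4	E327p	-0.932	53.11	1.055	61.08	1.844	62.05	-0.312	56.44	0.392	89.04	0.225	82.28
M5	Y771	-2.196	2.51	1.219	89.27	2.466	0.91	0.662	40.85	0.721	44.75	0.639	50.42
M5	T774	-4.253	5.82	2.437	101.3	3.602	61.71	1.128	44.86	1.071	91.96	0.857	76.09
M5	S775	3.068	-26.37	0.124	38.67	1.291	62.22
M5	N776	2.664	-166.23	0.918	87.15	1.709	62.85	-0.537	1.79	-0.495	50.76	-0.406	75.0
M5	E779p	-2.508	29.17	1.792	88.01	2.591	62.28	0.487	24.81	0.476	73.74	0.462	53.74
M6	D804	-3.895	-172.95	0.489	80.04	1.897	60.56	-0.197	82.91	-0.271	82.85	-0.193	79.47
M6	D804p	2.968	-157.98	0.532	81.76	1.835	60.45	-0.247	31.05	-0.296	89.84	-0.278	83.37
M6	N804	2.981	-160.18	0.371	84.0	1.451	59.42
M6	D808	-3.215	-159.94	0.215	7.87	1.744	59.13
M6	D808p	-2.298	55.97	1.204	66.88	2.446	2.53	0.746	37.74	0.715	55.74	0.627	63.72
M6	N808	-2.344	29.85	1.771	63.6	2.654	64.99	0.914	39.19	0.735	8.37	0.636	1.7
M8	Q923	-2.943	33.4	2.217	87.95	2.671	61.48	0.603	74.2	0.535	30.65	0.551	44.23
M8	D926	-4.361	-169.1	0.454	95.51	1.902	60.16	-0.283	92.02	-0.306	88.18	-0.215	85.37
M8	D926p	-2.704	28.74	1.477	93.38	2.744	61.08	0.816	58.99	0.852	58.37	0.809	58.93
M8	N926	3.674	-157.18	0.479	89.17	1.377	61.78	-0.625	82.59
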