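case_id	n_locus_pa	n_informative	n_assumed_pa	est_ff_lower_pct	est_ff_higher_pct	est_ff_combined_pct	n_loci_real_pa	n_real_informative	n_real_pa	n_dropout	n_dropin	detection_rate_pct	val_ff_lower_pct	val_ff_higher_pct	val_ff_combined_pct	ratio_printed
2	37	8	45	5.21	8.53	13.74	37	8	45	0	0	100.00	6.13	8.06	14.18	1.316
3	33	3	36	3.84	5.81	9.65	33	3	36	0	0	100.00	3.43	5.82	9.25	1.695
5	36	6	42	5.94	7.88	13.82	36	5	41	0	1	100.00	6.08	7.95	14.03	1.308
6	37	8	45	6.13	10.35	16.48	37	8	45	0	0	100.00	6.77	10.62	17.40	1.569
7	37	6	43	7.28	20.29	27.58	37	6	43	0	0	100.00	7.17	18.33	25.50	2.558
8	31	3	34	4.51	11.02	15.53	32	4	36	2	0	94.44	3.66	8.66	12.32	2.369
9	40	6	46	3.53	6.88	10.41	41	6	47	1	0	97.87	3.90	7.52	11.42	1.928
10	36	10	46	8.01	12.02	20.03	36	10	46	0	0	100.00	8.33	11.18	19.51	1.341
12	37	3	40	7.35	12.14	19.49	36	3	39	0	1	100.00	6.30	10.37	16.67	1.646
14	36	7	43	6.46	9.47	15.93	36	7	43	0	0	100.00	6.75	8.79	15.54	1.301
15	37	6	43	3.03	5.40	8.43	37	5	42	0	1	100.00	3.72	4.71	8.44	1.265
16	34	6	40	4.00	7.16	11.16	34	6	40	0	0	100.00	4.04	6.81	10.85	1.685
17	39	7	46	2.99	6.40	9.39	40	7	47	1	0	97.87	3.33	5.70	9.03	1.715
1	33	0	33	NA	NA	11.90	33	0	33	0	0	100.00	NA	NA	11.90	NA
4	31	0	31	NA	NA	15.96	31	0	31	0	0	100.00	NA	NA	15.96	NA
11	33	0	33	NA	NA	9.05	33	0	33	0	0	100.00	NA	NA	9.05	NA
13	38	0	38	NA	NA	18.08	38	0	38	0	0	100.00	NA	NA	18.08	NA
18	31	0	31	NA	NA	9.34	31	0	31	0	0	100.00	NA	NA	9.34	NA
19	34	0	34	NA	NA	11.90	34	0	34	0	0	100.00	NA	NA	11.90	NA
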