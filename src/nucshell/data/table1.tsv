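probe	condition	shell_1_pct	shell_2_pct	shell_3_pct	shell_4_pct	shell_5_pct
HSA1	24h	19.77	31.40	30.23	9.30	9.30
HSA1	7d	4.55	39.77	31.82	18.18	5.68
HSA3	24h	25.68	44.59	14.86	6.76	8.11
HSA3	7d	7.89	41.23	25.44	17.54	7.89
HSA7	24h	28.26	34.78	23.91	9.78	3.26
HSA7	7d	23.44	41.41	12.50	11.72	10.94
HSA11	24h	15.79	42.98	29.82	7.89	3.51
HSA11	7d	18.10	49.14	15.52	8.62	8.62
HSA12	24h	29.41	48.53	14.71	7.35	0.00
HSA12	7d	23.21	34.82	23.21	8.93	9.82
HSA17	24h	29.41	45.10	12.75	7.84	4.90
HSA17	7d	12.26	40.57	34.91	10.38	1.89
HSAX	24h	23.96	32.29	17.71	11.46	14.58
HSAX	7d	7.45	38.30	22.34	12.77	19.15
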