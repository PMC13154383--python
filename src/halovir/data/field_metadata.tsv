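site	date	season	temp_C	do_mg_per_L	salinity_ppt	pH	nh4_uM	no3_uM	no2_uM	autofluor_cells_per_mL	is_pulse	is_freeze
LOC	2020-05-01	Spring	28.33	5.86	64.99	8.3	44.35	2.4	0	80000	0	0
LOC	2020-06-01	Summer	30.8	4.12	66.16	8.55	47.77	2.1	0	60000	0	0
LOC	2020-09-01	Fall	30.2	0.7	69.3	8.12	36.9	1.8	0	85000	0	0
LOC	2020-10-01	Fall	27.5	0.57	70.5	7.9	8.21	3.11	0.08	35000	0	0
LOC	2021-01-01	Winter	18.8	3.25	70.46	8.33	14.09	4.55	0.82	225000	0	1
LOC	2021-02-01	Winter	22.2	4.45	71.22	8.38	9.61	9.04	0.05	2225000	0	1
LOC	2021-03-01	Spring	20.7	4.74	78.1	7.65	6.68	10.68	0.05	1025000	0	0
LOC	2021-06-01	Summer	29.9	2.33	2.57	8.66	8.7	2.19	0.05	25000	1	0
RB	2020-05-01	Spring	28.24	7.8	49.78	8.32	180.67	2.83	0.01	35000	0	0
RB	2020-06-01	Summer	28.93	6.53	47.77	8.17	156.48	2.45	0.06	5000	0	0
RB	2020-09-01	Fall	27.1	4.41	45.5	7.91	161.38	2.05	0	10000	0	0
RB	2020-10-01	Fall	26	4.12	43.8	8.06	22.37	2.4	0.27	5000	0	0
RB	2021-01-01	Winter	17.7	6	48.8	8.12	21.46	3.9	0.11	200000	0	1
RB	2021-02-01	Winter	20.93	7.25	49.3	8.17	17.49	7.45	0.19	15000	0	1
RB	2021-03-01	Spring	19.2	7.15	48.77	8.02	19.16	13.03	0.09	15000	0	0
RB	2021-06-01	Summer	28.8	5.92	16.05	8.37	30.39	1.81	0.02	20000	1	0
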