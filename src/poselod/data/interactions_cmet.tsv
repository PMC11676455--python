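drug	interaction	mean	dispersion	flag	diff
Cabozantinib	Asp1222:OD2	4.54	0.04	***	-3.55
Cabozantinib	His1202:NE2	4.54	0.05	***	-5.15
Cabozantinib	His1202:O1	5.95	0.01	***	-2.48
Cabozantinib	Leu1110:NZ	6.19	0.07	***	-2.41
Cabozantinib	Asp1202:N	4.77	0.06	***	-3.80
Cabozantinib	Asp1204:OD2	4.54	0.14	***	-5.15
Crizotinib	Asp1222:OD2	8.09	0.19	control	-
Crizotinib	His1202:NE2	9.69	0.22	control	-
Crizotinib	His1202:O1	8.43	0.25	control	-
Crizotinib	Leu1110:NZ	8.60	0.13	control	-
Crizotinib	Asp1202:N	8.57	0.19	control	-
Crizotinib	Asp1204:OD2	9.69	0.31	control	-
Dihydroergotamine	Asp1222:OD2	6.75	0.21	***	-1.34
Dihydroergotamine	His1202:NE2	6.75	0.04	***	-2.94
Dihydroergotamine	Asp1204:OD2	6.75	0.31	***	-2.94
Eltrombopag	His1202:NE2	8.75	0.22	***	-0.94
Eltrombopag	His1202:O1	6.65	0.13	***	-1.78
Eltrombopag	Leu1110:NZ	3.86	0.12	***	-4.74
Eltrombopag	Asp1202:N	6.58	0.15	***	-1.99
Eltrombopag	Asp1204:OD2	8.75	0.05	***	-0.94
Entacapone	His1202:NE2	5.30	0.03	***	-4.39
Entacapone	His1202:O1	3.51	0.22	***	-4.92
Entacapone	Leu1110:NZ	6.71	0.08	***	-1.89
Entacapone	Asp1202:N	3.47	0.04	***	-5.10
Entacapone	Asp1204:OD2	5.30	0.62	***	-4.39
Fludarabine Phosphate	His1202:NE2	8.49	0.14	***	-1.20
Fludarabine Phosphate	His1202:O1	13.18	0.23	***	4.75
Fludarabine Phosphate	Leu1110:NZ	13.59	0.30	***	4.99
Fludarabine Phosphate	Asp1202:N	12.88	0.17	***	4.31
Fludarabine Phosphate	Asp1204:OD2	8.49	0.29	***	-1.20
Mizolastine	Asp1222:OD2	3.89	0.06	***	-4.20
Mizolastine	His1202:NE2	4.02	0.06	***	-5.67
Mizolastine	Leu1110:NZ	6.32	0.08	***	-2.28
Mizolastine	Asp1204:OD2	4.02	0.41	***	-5.67
Oxandrolone	His1202:O1	5.84	0.16	***	-2.59
Oxandrolone	Leu1110:NZ	5.83	0.10	***	-2.77
Oxandrolone	Asp1202:N	3.67	0.11	***	-4.90
Salsalate	Asp1222:OD2	6.32	0.32	***	-1.77
Salsalate	His1202:NE2	6.34	0.21	***	-3.35
Salsalate	Leu1110:NZ	7.33	0.24	***	-1.27
Salsalate	Asp1202:N	8.72	0.18	NS	0.15
Salsalate	Asp1204:OD2	6.34	0.43	***	-3.35
Telmisartan	His1202:NE2	6.11	0.23	***	-3.58
Telmisartan	His1202:O1	7.85	0.31	***	-0.58
Telmisartan	Leu1110:NZ	7.21	0.22	***	-1.39
Telmisartan	Asp1202:N	8.39	0.51	NS	-0.18
Telmisartan	Asp1204:OD2	6.11	0.33	***	-3.58
Triamterene	Asp1222:OD2	4.54	0.24	***	-3.55
Triamterene	His1202:NE2	6.07	0.17	***	-3.62
Triamterene	His1202:O1	3.05	0.34	***	-5.38
Triamterene	Leu1110:NZ	6.99	0.12	***	-1.61
Triamterene	Asp1204:OD2	6.07	0.23	***	-3.62
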