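drug	interaction	mean	dispersion	flag	diff
Cabozantinib	Cys919:SG	18.76	0.34	control	-
Cabozantinib	Cys1024:SG	8.94	0.18	control	-
Cabozantinib	Lys868:NZ	11.32	0.06	control	-
Cabozantinib	Asp1028:OD2	10.78	0.14	control	-
Cabozantinib	Asp1046:OD2	6.81	0.17	control	-
Telmisartan	Cys919:SG	13.35	0.12	***	-5.41
Telmisartan	Cys1024:SG	7.22	0.10	***	-1.72
Telmisartan	Lys868:NZ	9.64	0.11	***	-1.68
Telmisartan	Asp1046:OD2	3.78	0.04	***	-3.03
Entacapone	Cys919:SG	18.50	0.07	NS	-0.26
Entacapone	Cys1024:SG	4.22	0.08	***	-4.72
Entacapone	Lys868:NZ	10.02	0.10	***	-1.30
Eltrombopag	Cys919:SG	19.68	0.137	***	0.92
Eltrombopag	Cys1024:SG	16.54	0.24	***	7.60
Eltrombopag	Lys868:NZ	11.02	0.16	***	-0.30
Triamterene	Cys919:SG	20.27	0.09	***	1.51
Triamterene	Lys868:NZ	17.20	0.06	***	5.88
Triamterene	Asp1028:OD2	3.84	0.07	***	-6.94
Triamterene	Asp1046:OD2	8.89	0.06	***	2.08
Crizotinib	Cys919:SG	20.59	0.11	***	1.83
Crizotinib	Cys1024:SG	14.39	0.10	***	5.45
Crizotinib	Lys868:NZ	12.14	0.20	***	0.82
Crizotinib	Asp1028:OD2	4.59	0.07	***	-6.19
Crizotinib	Asp1046:OD2	8.47	0.12	***	1.66
Dihydroergotamine	Cys919:SG	13.99	0.05	***	-4.77
Dihydroergotamine	Lys868:NZ	18.17	0.05	***	6.85
Dihydroergotamine	Asp1028:OD2	10.66	0.04	NS	-0.12
Fludarabine Phosphate	Lys868:NZ	11.81	0.26	***	0.49
Fludarabine Phosphate	Asp1046:OD2	8.15	0.16	***	1.34
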