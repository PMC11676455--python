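drug	affinity_cmet	affinity_vegfr2	proximity_cmet	proximity_vegfr2	lod_cmet	lod_vegfr2
Cabozantinib	-7.7	-8.2	3.1	2.9	-0.55	-0.52
Crizotinib	-7.9	-7.5	2.4	3.1	-0.64	-0.60
Telmisartan	-7.3	-7.8	3.2	2.8	-15.3	-18.7
Triamterene	-8.0	-8.3	2.5	2.7	-0.50	-0.6
Dihydroergotamine	-7.6	-7.4	2.9	3.0	-12.5	-11.8
Oxandrolone	-7.7	-7.1	3.3	3.5	-5.7	-8.2
Mizolastine	-7.0	-7.3	3.1	2.7	-8.2	-10.4
Fludarabine Phosphate	-7.4	-7.0	2.3	2.6	-6.64	-9.62
Eltrombopag	-7.8	-8.0	2.7	2.5	-22.3	-25.1
Entacapone	-7.5	-7.2	2.2	2.4	-19.0	-17.5
Salsalate	-6.8	-6.6	3.4	3.6	-37.18	-40.5
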