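QTL	CHR	N_QTLs	N_QTLs_db	Total_annotated_QTLs	Total_QTLs_db	QTL_type
Scrotal circumference	5	132	134	347	5942	Reproduction
Scrotal circumference	18	11	13	41	2147	Reproduction
Scrotal circumference	9	11	14	30	1395	Reproduction
Milk glycosylated kappa-casein percentage	6	71	1607	204	12158	Milk
Inhibin level	5	47	285	347	5942	Reproduction
Scrotal circumference	21	4	5	12	3606	Reproduction
Milk kappa-casein percentage	6	76	2637	204	12158	Milk
Triglyceride level	5	6	7	347	5942	Health
Milk glycosylated kappa-casein percentage	16	7	44	21	1440	Milk
Milk iron content	23	4	8	19	1159	Milk
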