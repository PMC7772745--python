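1	toy	gene	110000	115000	.	+	.	gene_id "TG01"; gene_name "R1A"; gene_biotype "protein_coding";
1	toy	gene	130000	140000	.	-	.	gene_id "TG02"; gene_name "R1B"; gene_biotype "protein_coding";
1	toy	gene	150000	160000	.	+	.	gene_id "TG03"; gene_name "R1C"; gene_biotype "protein_coding";
1	toy	gene	190000	210000	.	+	.	gene_id "TG04"; gene_name "R1D"; gene_biotype "protein_coding";
1	toy	gene	290000	310000	.	-	.	gene_id "TG05"; gene_name "R2A"; gene_biotype "protein_coding";
1	toy	gene	320000	330000	.	+	.	gene_id "TG06"; gene_name "R2B"; gene_biotype "protein_coding";
1	toy	gene	350000	360000	.	-	.	gene_id "TG07"; gene_name "R2C"; gene_biotype "protein_coding";
1	toy	gene	395000	405000	.	+	.	gene_id "TG08"; gene_name "R2D"; gene_biotype "protein_coding";
2	toy	gene	100500	101000	.	+	.	gene_id "TG09"; gene_name "R3A"; gene_biotype "protein_coding";
2	toy	gene	120000	125000	.	-	.	gene_id "TG10"; gene_name "R3B"; gene_biotype "protein_coding";
2	toy	gene	140000	150000	.	+	.	gene_id "TG11"; gene_name "R3C"; gene_biotype "protein_coding";
2	toy	gene	199000	200000	.	+	.	gene_id "TG12"; gene_name "R3D"; gene_biotype "protein_coding";
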