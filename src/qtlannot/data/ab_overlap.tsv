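group	gene_id
A	G1
A	G2
A	G3
A	G4
A	G5
A	G6
A	G7
A	G8
A	G9
A	G10
B	G6
B	G7
B	G8
B	G9
B	G10
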