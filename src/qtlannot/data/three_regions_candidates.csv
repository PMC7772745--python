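CHR,BP1,BP2,study
1,100000,200000,studyA
1,300000,400000,studyA
2,100000,200000,studyB
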