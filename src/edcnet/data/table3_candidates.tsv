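score	chemical	cas	interacting_genes
40	Perfluorooctanoic acid	335-67-1	ABCG1;APOB;CYP1A1;ERBB2;ESR1;TP53;SHH
37	Stearic acid	57-11-4	ABCG1;AKT1;AR;ESR1
35	Triphenyl phosphate	115-86-6	AR;ESR1;TP53
34	Dibutyl Phthalate	84-74-2	AKT1;AR;ESR1
30	Sodium Fluoride	7681-49-4	AKT1;CASP8;TP53;FAS
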