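name	smiles
Caffeine	CN1C=NC2=C1C(=O)N(C)C(=O)N2C
Theobromine	CN1C=NC2=C1C(=O)NC(=O)N2C
Theophylline	CN1C(=O)N(C)C2=C1N=CN2
Kaempferol	O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12
Quercetin	O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12
Nicotiflorin	C[C@@H]1O[C@@H](OC[C@H]2O[C@@H](Oc3c(-c4ccc(O)cc4)oc4cc(O)cc(O)c4c3=O)[C@H](O)[C@@H](O)[C@@H]2O)[C@H](O)[C@H](O)[C@H]1O
Rutin	C[C@@H]1O[C@@H](OC[C@H]2O[C@@H](Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)[C@H](O)[C@@H](O)[C@@H]2O)[C@H](O)[C@H](O)[C@H]1O
Acetyl-L-carnitine	CC(=O)O[C@H](CC([O-])=O)C[N+](C)(C)C
Butanoyl-L-carnitine	CCCC(=O)O[C@H](CC([O-])=O)C[N+](C)(C)C
Propanoyl-L-carnitine	CCC(=O)O[C@H](CC([O-])=O)C[N+](C)(C)C
Isovaleryl-L-carnitine	CC(C)CC(=O)O[C@H](CC([O-])=O)C[N+](C)(C)C
Valeryl-L-carnitine	CCCCC(=O)O[C@H](CC([O-])=O)C[N+](C)(C)C
L-Carnitine	C[N+](C)(C)C[C@H](O)CC([O-])=O
Methionine sulfoxide	CS(=O)CC[C@H](N)C(O)=O
Pipecolic acid	OC(=O)C1CCCCN1
Betaine	C[N+](C)(C)CC([O-])=O
Cysteinolic acid	NC(CO)CS(=O)(=O)O
N,N-Dimethylarginine	CN(C)C(=N)NCCC[C@H](N)C(O)=O
1-Chlorobenzotriazole	Cln1nnc2ccccc21
4-Hydroxycinnamic acid	OC(=O)/C=C/c1ccc(O)cc1
Caffeic acid	OC(=O)/C=C/c1ccc(O)c(O)c1
Ferulic acid	COc1cc(/C=C/C(O)=O)ccc1O
Linoleic acid	CCCCC/C=C\C/C=C\CCCCCCCC(O)=O
Palmitic acid	CCCCCCCCCCCCCCCC(O)=O
Stearic acid	CCCCCCCCCCCCCCCCCC(O)=O
Oleic acid	CCCCCCCC/C=C\CCCCCCCC(O)=O
Glyceryl monolinoleate	CCCCC/C=C\C/C=C\CCCCCCCC(=O)OCC(O)CO
Glucose	OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O
Sucrose	OC[C@H]1O[C@@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O
Citric acid	OC(=O)CC(O)(CC(O)=O)C(O)=O
Malic acid	OC(CC(O)=O)C(O)=O
Fumaric acid	OC(=O)/C=C/C(O)=O
Succinic acid	OC(=O)CCC(O)=O
Lactic acid	CC(O)C(O)=O
Pyruvic acid	CC(=O)C(O)=O
Alanine	C[C@H](N)C(O)=O
Glycine	NCC(O)=O
Serine	OC[C@H](N)C(O)=O
Threonine	C[C@@H](O)[C@H](N)C(O)=O
Valine	CC(C)[C@H](N)C(O)=O
Leucine	CC(C)C[C@H](N)C(O)=O
Isoleucine	CC[C@H](C)[C@H](N)C(O)=O
Proline	OC(=O)[C@@H]1CCCN1
Phenylalanine	N[C@@H](Cc1ccccc1)C(O)=O
Tyrosine	N[C@@H](Cc1ccc(O)cc1)C(O)=O
Tryptophan	N[C@@H](Cc1c[nH]c2ccccc12)C(O)=O
Histidine	N[C@@H](Cc1c[nH]cn1)C(O)=O
Lysine	NCCCC[C@H](N)C(O)=O
Arginine	N=C(N)NCCC[C@H](N)C(O)=O
Aspartic acid	N[C@@H](CC(O)=O)C(O)=O
Glutamic acid	N[C@@H](CCC(O)=O)C(O)=O
Glutamine	NC(=O)CC[C@H](N)C(O)=O
Asparagine	NC(=O)C[C@H](N)C(O)=O
Methionine	CSCC[C@H](N)C(O)=O
Cysteine	N[C@@H](CS)C(O)=O
Glutathione	N[C@@H](CCC(=O)N[C@@H](CS)C(=O)NCC(O)=O)C(O)=O
Adenine	Nc1ncnc2[nH]cnc12
Guanine	Nc1nc2[nH]cnc2c(=O)[nH]1
Cytosine	Nc1cc[nH]c(=O)n1
Uracil	O=c1cc[nH]c(=O)[nH]1
Thymine	Cc1c[nH]c(=O)[nH]c1=O
Adenosine	Nc1ncnc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O
Inosine	O=c1[nH]cnc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O
Hypoxanthine	O=c1[nH]cnc2nc[nH]c12
Xanthine	O=c1[nH]c(=O)c2[nH]cnc2[nH]1
Uric acid	O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1
Nicotinic acid	OC(=O)c1cccnc1
Nicotinamide	NC(=O)c1cccnc1
Pyridoxine	Cc1ncc(CO)c(CO)c1O
Riboflavin	Cc1cc2nc3c(=O)[nH]c(=O)n(C[C@H](O)[C@H](O)[C@H](O)CO)c3nc2cc1C
Pantothenic acid	CC(C)(CO)[C@@H](O)C(=O)NCCC(O)=O
Biotin	O=C1N[C@@H]2[C@H](CCCCC(O)=O)SC[C@@H]2N1
Folic acid	Nc1nc2ncc(CNc3ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc3)nc2c(=O)[nH]1
Ascorbic acid	OC[C@H](O)[C@H]1OC(=O)C(O)=C1O
Cholesterol	C[C@H](CCCC(C)C)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](O)CC[C@]4(C)[C@H]3CC[C@]12C
Cortisol	C[C@]12C[C@H](O)[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CC[C@]2(O)C(=O)CO
Testosterone	C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CC[C@@H]2O
Estradiol	C[C@]12CC[C@H]3c4ccc(O)cc4CC[C@H]3[C@@H]1CC[C@@H]2O
Dopamine	NCCc1ccc(O)c(O)c1
Serotonin	NCCc1c[nH]c2ccc(O)cc12
Epinephrine	CNC[C@H](O)c1ccc(O)c(O)c1
Melatonin	COc1ccc2[nH]cc(CCNC(C)=O)c2c1
Histamine	NCCc1c[nH]cn1
Tryptamine	NCCc1c[nH]c2ccccc12
Choline	C[N+](C)(C)CCO
Acetylcholine	CC(=O)OCC[N+](C)(C)C
Creatine	CN(CC(O)=O)C(=N)N
Creatinine	CN1CC(=O)N=C1N
Taurine	NCCS(O)(=O)=O
Carnosine	N[C@@H](Cc1c[nH]cn1)NC(=O)CCN
Citrulline	NC(=O)NCCC[C@H](N)C(O)=O
Ornithine	NCCC[C@H](N)C(O)=O
Spermidine	NCCCCNCCCN
Putrescine	NCCCCN
Salicylic acid	OC(=O)c1ccccc1O
Benzoic acid	OC(=O)c1ccccc1
Vanillin	COc1cc(C=O)ccc1O
Gallic acid	OC(=O)c1cc(O)c(O)c(O)c1
Chlorogenic acid	O=C(/C=C/c1ccc(O)c(O)c1)O[C@@H]1C[C@@](O)(C(O)=O)C[C@H](O)[C@H]1O
Resveratrol	Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1
Naringenin	O=C1C[C@H](c2ccc(O)cc2)Oc2cc(O)cc(O)c21
Apigenin	O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12
Luteolin	O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12
Catechin	Oc1cc(O)c2c(c1)O[C@H](c1ccc(O)c(O)c1)[C@H](O)C2
Menthol	CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O
Limonene	CC(=C)[C@@H]1CCC(C)=CC1
Camphor	CC1(C)[C@@H]2CC[C@@]1(C)C(=O)C2
Indole-3-acetic acid	OC(=O)Cc1c[nH]c2ccccc12
Abscisic acid	CC1=CC(=O)CC(C)(C)[C@@]1(O)/C=C/C(C)=C\C(O)=O
Dihydrostilbene-2-ol	Oc1ccc(CCc2ccccc2O)cc1
Bibenzyl-3,4'-diol	Oc1ccc(CCc2cccc(O)c2)cc1
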