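# synthetic stand-in structure table: structure_key <TAB> SMILES
# small molecules chosen to span a range of pairwise Tanimoto similarities
S01	CCO
S02	CCN
S03	CCCO
S04	CC(C)O
S05	c1ccccc1
S06	c1ccccc1O
S07	c1ccccc1N
S08	CC(=O)Oc1ccccc1C(=O)O
S09	CC(=O)Nc1ccc(O)cc1
S10	CN1C=NC2=C1C(=O)N(C)C(=O)N2C
S11	OC(=O)c1ccccc1O
S12	NCC(=O)O
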