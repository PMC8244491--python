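# Manifest of the 13 experimentally reported OR1A2 agonists (terpenes,
# alcohols and aldehydes). Names and SMILES curated from the OR
# deorphanization literature; the three best-characterised agonists
# ((S)-(-)-citronellal, helional, octanal) are first. SMILES are
# indicative reference structures; users validating against primary
# sources should supply their own SDF.
# version: 1
id	smiles
S-citronellal	O=CC[C@@H](C)CCC=C(C)C
helional	O=CC(C)Cc1ccc2OCOc2c1
octanal	CCCCCCCC=O
R-citronellal	O=CC[C@H](C)CCC=C(C)C
citronellol	OCCC(C)CCC=C(C)C
geraniol	OC/C=C(C)/CCC=C(C)C
nerol	OC/C=C(\C)CCC=C(C)C
geranial	O=C/C=C(C)/CCC=C(C)C
neral	O=C/C=C(\C)CCC=C(C)C
nonanal	CCCCCCCCC=O
heptanal	CCCCCCC=O
linalool	CC(C)=CCCC(C)(O)C=C
citronellic-acid	OC(=O)CC(C)CCC=C(C)C
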